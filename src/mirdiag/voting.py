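"""Stability voting for biomarker selection.

Repeated stratified K-fold resampling of the training cohort: within every
fold's training portion a two-stage candidate selection runs — (1) the
univariate logistic screen keeps features passing the FDR threshold, (2) a
SCAD-penalized linear SVM with GCV-tuned lambda keeps the features with
nonzero coefficients.  Every feature's selection count over all
``n_folds * n_repeats`` candidate sets is its voting score; markers are
ranked by count (ties broken by full-cohort univariate AUC, then feature
id).  With the defaults (5 folds x 200 repeats) this yields 1000 candidate
sets, and the top of the ranking is the diagnostic marker panel.

Both selection stages are recomputed inside every fold from that fold's
training samples only; the held-out fold never influences its candidate
set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DEAConfig, adjust_fdr, logistic_screen, marker_auc
from .scad import ScadSolverConfig, select_lambda_gcv

__all__ = [
    "VotingConfig",
    "CandidateSet",
    "make_stratified_folds",
    "candidate_selection_one_fold",
    "run_voting",
    "top_k",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VotingConfig:
    n_folds: int = 5
    n_repeats: int = 200
    fdr_threshold: float = 0.05
    seed: int = 0
    scad_config: ScadSolverConfig = field(default_factory=ScadSolverConfig)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        DEAConfig(self.fdr_threshold)  # validates the threshold

    @property
    def n_candidate_sets(self) -> int:
        return self.n_folds * self.n_repeats


@dataclass(frozen=True)
class CandidateSet:
    repeat_index: int
    fold_index: int
    feature_ids: frozenset[str]


def make_stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment.

    Fold sizes differ by at most one overall and within each class.
    Returns an integer vector of fold indices in ``[0, n_folds)``.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels)
    for cls in np.unique(y):
        if (y == cls).sum() < n_folds:
            raise ValueError(
                f"class {cls!r} has {(y == cls).sum()} samples, fewer than n_folds={n_folds}"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**32))
    assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = f
    return assignment


def candidate_selection_one_fold(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    config: VotingConfig,
) -> frozenset[str]:
    """FDR screen then SCAD-SVM selection on one fold's training samples.

    ``train_X`` is features x samples.  Returns the feature ids with
    nonzero SCAD-SVM coefficients; empty when nothing passes the FDR
    screen (no SCAD fit is attempted then).
    """
    y = np.asarray(train_y)
    _, pvals = logistic_screen(train_X.to_numpy(), y)
    qvals = adjust_fdr(pvals)
    keep = qvals < config.fdr_threshold
    if not keep.any():
        logger.info("no feature passed FDR %.3g in this fold", config.fdr_threshold)
        return frozenset()
    ids = train_X.index[keep]
    sub = train_X.loc[ids].to_numpy().T  # samples x features for the SVM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, model = select_lambda_gcv(sub, y, config.scad_config)
    return frozenset(ids[list(model.support)])


def run_voting(
    expression: pd.DataFrame,
    labels: np.ndarray,
    config: VotingConfig = VotingConfig(),
) -> tuple[pd.DataFrame, list[CandidateSet]]:
    """Run the full voting scheme.

    Parameters
    ----------
    expression : DataFrame, features x samples (training cohort only).
    labels : binary vector over samples.

    Returns
    -------
    frequency_table : DataFrame
        Indexed by feature id (ever-selected features only), columns
        ``selection_count``, ``auc`` (full-cohort univariate AUC, the tie
        break), ``rank`` (1 = most frequently selected).
    candidate_sets : list of CandidateSet
        Full provenance, ``n_folds * n_repeats`` entries (failed folds are
        recorded as empty sets and logged; the denominator is unchanged).
    """
    y = np.asarray(labels)
    root = np.random.SeedSequence(config.seed)
    repeat_seeds = root.generate_state(config.n_repeats) >> 1  # keep < 2**31
    counts: dict[str, int] = {}
    provenance: list[CandidateSet] = []
    n_failures = 0
    for r in range(config.n_repeats):
        folds = make_stratified_folds(y, config.n_folds, int(repeat_seeds[r]))
        for f in range(config.n_folds):
            train_mask = folds != f
            try:
                selected = candidate_selection_one_fold(
                    expression.loc[:, train_mask], y[train_mask], config
                )
            except Exception:  # pragma: no cover - defensive
                logger.warning("candidate selection failed (repeat %d fold %d)",
                               r, f, exc_info=True)
                n_failures += 1
                selected = frozenset()
            provenance.append(CandidateSet(r, f, selected))
            for fid in selected:
                counts[fid] = counts.get(fid, 0) + 1
    if n_failures:
        logger.warning("%d of %d candidate selections failed and count as empty",
                       n_failures, config.n_candidate_sets)

    if counts:
        aucs = {fid: marker_auc(expression.loc[fid].to_numpy(), y)[0] for fid in counts}
        table = pd.DataFrame(
            {"selection_count": pd.Series(counts), "auc": pd.Series(aucs)}
        )
        table.index.name = "feature_id"
        table = table.sort_values(
            by=["selection_count", "auc"], ascending=[False, False], kind="stable"
        )
        # stable sort + sorted index inside tie groups -> deterministic ranks
        table = (
            table.reset_index()
            .sort_values(["selection_count", "auc", "feature_id"],
                         ascending=[False, False, True], kind="stable")
            .set_index("feature_id")
        )
        table["rank"] = np.arange(1, len(table) + 1)
    else:
        table = pd.DataFrame(columns=["selection_count", "auc", "rank"])
        table.index.name = "feature_id"
    return table, provenance


def top_k(frequency_table: pd.DataFrame, k: int) -> list[str]:
    """The first ``k`` feature ids by rank."""
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    if k > len(frequency_table):
        warnings.warn(
            f"K={k} exceeds the {len(frequency_table)} ever-selected features; "
            "returning all of them"
        )
        k = len(frequency_table)
    ranked = frequency_table.sort_values("rank", kind="stable")
    return list(ranked.index[:k])
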