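"""RBF-kernel SVM diagnosis on a ranked marker panel.

Given markers ranked by stability voting, the diagnostic stage builds an
RBF-kernel SVM on the top-K markers.  Hyperparameters (kernel width gamma
and soft-margin cost) come from an exhaustive inner cross-validated grid
search maximizing AUC; the panel size K is chosen by outer
cross-validation repeated over reseeded fold partitions (double / nested
cross-validation, so every reported test metric comes from samples that
influenced neither feature scaling, hyperparameters, nor calibration).
Decision values are mapped to diagnosis probabilities by a two-parameter
Platt sigmoid fitted on cross-validated decision values; the probability
cutoff is picked from a small candidate set by balanced accuracy.  The
final model is refit on the whole training cohort and applied to an
external validation cohort, with a stratified-bootstrap ROC confidence
band and a scalar-comparator diagnosis (a CA19-9-style cutoff rule) for
reference.

Kernel evaluations are organized around precomputed pairwise squared
distances: the top-K distance matrix for every K is a cumulative sum over
ranked features, and each gamma only needs an elementwise exponential,
which keeps the 21 x 15 grid x 5 inner folds x K-path affordable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .diffexpr import roc_auc
from .voting import make_stratified_folds

__all__ = [
    "GridSpec",
    "DoubleCVConfig",
    "DiagnosticModel",
    "ValidationReport",
    "ComparatorSpec",
    "inner_grid_search",
    "double_cv",
    "choose_k",
    "choose_threshold",
    "fit_final",
    "validate",
    "comparator_diagnosis",
    "sensitivity_specificity",
]

DEFAULT_THRESHOLD_CANDIDATES = (0.5, 0.55, 0.6, 0.65, 0.7)


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid: powers of two, 21 gammas x 15 costs."""

    gamma_values: tuple[float, ...] = tuple(2.0 ** e for e in range(-10, 11))
    cost_values: tuple[float, ...] = tuple(2.0 ** e for e in range(-7, 8))

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gamma_values) or any(c <= 0 for c in self.cost_values):
            raise ValueError("gamma and cost values must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.gamma_values) * len(self.cost_values)


@dataclass(frozen=True)
class DoubleCVConfig:
    outer_folds: int = 5
    inner_folds: int = 5
    n_repeats: int = 20
    k_range: tuple[int, ...] = tuple(range(2, 51))
    candidate_thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_CANDIDATES
    threshold: float = 0.5  # probability cutoff used for sens/spec inside the CV
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_range, default=0) < 1:
            raise ValueError("k_range entries must be >= 1")
        if any(not (0.0 < t < 1.0) for t in self.candidate_thresholds):
            raise ValueError("candidate thresholds must lie in (0, 1)")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Platt sigmoid calibration


def platt_fit(decision_values: np.ndarray, labels01: np.ndarray) -> tuple[float, float]:
    """Fit P(case | f) = 1 / (1 + exp(A f + B)) by penalized log-loss.

    Uses Platt's smoothed targets ((N+ + 1)/(N+ + 2) for cases) so the fit
    is well defined even on separable decision values.  Deterministic.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels01, dtype=float)
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    # convex in (a, b): damped Newton, deterministic start
    a, b = -1.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))

    # p = P(case) = 1/(1+e^z), z = a f + b; cross-entropy against targets t:
    # nll = sum t*z + log(1+e^-z)
    def nll(a_, b_):
        z = a_ * f + b_
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    current = nll(a, b)
    for _ in range(100):
        z = a * f + b
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # = P(case)
        # d nll / dz = t - p ; weights p(1-p)
        g = t - p
        w = np.maximum(p * (1.0 - p), 1e-12)
        ga, gb = float(g @ f), float(g.sum())
        haa, hab, hbb = float(w @ (f * f)), float(w @ f), float(w.sum())
        det = haa * hbb - hab * hab
        if det <= 1e-20:
            break
        da = -(hbb * ga - hab * gb) / det
        db = -(haa * gb - hab * ga) / det
        step = 1.0
        for _ in range(30):
            cand = nll(a + step * da, b + step * db)
            if cand <= current + 1e-12:
                break
            step *= 0.5
        a, b = a + step * da, b + step * db
        if abs(current - cand) < 1e-12 and max(abs(step * da), abs(step * db)) < 1e-10:
            current = cand
            break
        current = cand
    return float(a), float(b)


def platt_apply(decision_values: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(decision_values, dtype=float) + b
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


# ---------------------------------------------------------------------------
# metrics


def sensitivity_specificity(
    probabilities: np.ndarray, labels01: np.ndarray, threshold: float
) -> tuple[float, float]:
    """Sensitivity and specificity of ``probability > threshold``.

    Either is NaN when its class is absent.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels01, dtype=int)
    call = p > threshold
    with np.errstate(invalid="ignore"):
        sens = float(call[y == 1].mean()) if (y == 1).any() else float("nan")
        spec = float((~call[y == 0]).mean()) if (y == 0).any() else float("nan")
    return sens, spec


# ---------------------------------------------------------------------------
# kernel helpers


def _pairwise_sq_cumulative(Z: np.ndarray, ks: list[int]) -> dict[int, np.ndarray]:
    """Cumulative pairwise squared distances over the first k columns of Z."""
    n = Z.shape[0]
    out: dict[int, np.ndarray] = {}
    acc = np.zeros((n, n))
    for j in range(Z.shape[1]):
        col = Z[:, j]
        diff = col[:, None] - col[None, :]
        acc = acc + diff * diff
        if (j + 1) in ks:
            out[j + 1] = acc.copy()
    return out


def _svc_fit_precomputed(K_train: np.ndarray, y_train: np.ndarray, cost: float) -> SVC:
    svc = SVC(kernel="precomputed", C=cost)
    svc.fit(K_train, y_train)
    return svc


try:  # fast path: the low-level libsvm binding skips estimator overhead
    from sklearn.svm import _libsvm as _libsvm_mod

    _libsvm_mod.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - depends on sklearn internals
    _libsvm_mod = None


def _svm_decision(
    K_train: np.ndarray, y_train01: np.ndarray, K_test: np.ndarray, cost: float
) -> np.ndarray:
    """Decision values on ``K_test`` rows, positive toward class 1.

    Identical (to float precision) to ``SVC(kernel="precomputed",
    C=cost).fit(K_train, y).decision_function(K_test)``; uses the
    low-level libsvm binding when available because the estimator wrapper
    dominates runtime in grid searches.  The binding's binary decision
    sign is opposite to the estimator convention; unit tests pin the
    equivalence against ``SVC``.
    """
    if _libsvm_mod is None:  # pragma: no cover
        svc = _svc_fit_precomputed(K_train, y_train01, cost)
        return svc.decision_function(K_test)
    fit_out = _libsvm_mod.fit(
        np.ascontiguousarray(K_train, dtype=np.float64),
        np.ascontiguousarray(y_train01, dtype=np.float64),
        svm_type=0,
        kernel="precomputed",
        C=cost,
    )
    support, SV, nSV, sv_coef, intercept, probA, probB = fit_out[:7]
    dec = _libsvm_mod.decision_function(
        np.ascontiguousarray(K_test, dtype=np.float64),
        support, SV, nSV, sv_coef, intercept, probA, probB,
        svm_type=0, kernel="precomputed",
    )
    return -dec.ravel()


# ---------------------------------------------------------------------------
# inner grid search


def inner_grid_search(
    D2: np.ndarray,
    y: np.ndarray,
    grid: GridSpec,
    inner_folds: int,
    seed: int,
) -> tuple[float, float, np.ndarray]:
    """Exhaustive (gamma, cost) search by mean inner-CV AUC.

    ``D2`` is the precomputed pairwise squared-distance matrix of the
    training samples (on standardized top-K markers); ``y`` their 0/1
    labels.  Returns the winning pair and that pair's out-of-fold decision
    values, which the caller reuses for probability calibration.

    AUC saturates at 1 over large grid regions on well-separated data, so
    exact ties are routine.  Ties resolve by mean inner-CV accuracy first
    — AUC is insensitive to the decision intercept, and the heavily
    regularized corner of the grid produces near-zero decision values
    whose arbitrary intercepts ruin both accuracy and any later
    probability calibration — then to the smaller cost, then the smaller
    gamma.
    """
    y = np.asarray(y, dtype=int)
    folds = make_stratified_folds(y, inner_folds, seed)
    for f in range(inner_folds):
        if len(np.unique(y[folds == f])) < 2:
            raise ValueError("degenerate inner fold: one class missing")
    n_g, n_c = len(grid.gamma_values), len(grid.cost_values)
    fold_auc = np.zeros((n_g, n_c, inner_folds))
    fold_acc = np.zeros((n_g, n_c, inner_folds))
    decisions = np.zeros((n_g, n_c, len(y)))
    for gi, gamma in enumerate(grid.gamma_values):
        K = np.exp(-gamma * D2)
        for f in range(inner_folds):
            te = folds == f
            tr = ~te
            K_tr = K[np.ix_(tr, tr)]
            K_te = K[np.ix_(te, tr)]
            y_tr, y_te = y[tr], y[te]
            for ci, cost in enumerate(grid.cost_values):
                dec = _svm_decision(K_tr, y_tr, K_te, cost)
                decisions[gi, ci, te] = dec
                fold_auc[gi, ci, f] = roc_auc(dec, y_te)
                fold_acc[gi, ci, f] = float(((dec > 0).astype(int) == y_te).mean())
    mean_auc = fold_auc.mean(axis=2)
    mean_acc = fold_acc.mean(axis=2)
    best = mean_auc.max()
    tied = mean_auc >= best - 1e-12
    best_acc = mean_acc[tied].max()
    ties = np.argwhere(tied & (mean_acc >= best_acc - 1e-12))
    ci, gi = min((c, g) for g, c in ties)
    return (
        float(grid.gamma_values[gi]),
        float(grid.cost_values[ci]),
        decisions[gi, ci].copy(),
    )


# ---------------------------------------------------------------------------
# double (nested) cross-validation


def double_cv(
    expression: pd.DataFrame,
    labels: np.ndarray,
    ranked_markers: list[str],
    config: DoubleCVConfig = DoubleCVConfig(),
    grid: GridSpec = GridSpec(),
    ranking: str = "given",
    refit_voting=None,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Estimate test performance of the top-K panel for every K.

    For each repeat and outer fold, and for each K in ``config.k_range``:
    the top-K markers are standardized on the outer-training part, (gamma,
    cost) are tuned by :func:`inner_grid_search` there, a Platt sigmoid is
    fitted on the tuned pair's out-of-fold decision values, the model is
    refit on the whole outer-training part and scored on the untouched
    outer-test fold.  AUC is threshold-free; sensitivity/specificity use
    ``config.threshold``.

    ``ranking`` controls where the marker ranking comes from:

    - ``"given"``: ``ranked_markers`` as supplied, i.e. a ranking computed
      once on the whole training cohort.  This mirrors reusing a published
      global ranking and carries the mild selection bias of ranking on
      data the outer folds will test on.
    - ``"refit"``: the stability-voting ranking is recomputed inside every
      outer-training part (``refit_voting`` supplies the VotingConfig),
      padded by outer-training univariate AUC when voting selects fewer
      than max(K) markers; leakage-free but far costlier.

    Returns
    -------
    summary : DataFrame indexed by K with columns ``mean_auc, sd_auc,
        mean_sensitivity, mean_specificity, mean_accuracy`` (accuracy =
        (sensitivity + specificity) / 2, averaged with equal fold weight).
    oof : dict K -> DataFrame with pooled out-of-fold ``probability``,
        ``label``, ``repeat`` columns, for threshold selection.
    """
    if ranking not in ("given", "refit"):
        raise ValueError(f"unknown ranking mode {ranking!r}")
    if ranking == "refit" and refit_voting is None:
        raise ValueError("ranking='refit' requires a refit_voting VotingConfig")
    y = np.asarray(labels, dtype=int)
    ks = sorted(set(config.k_range))
    if ranking == "given" and ks[-1] > len(ranked_markers):
        raise ValueError(
            f"K={ks[-1]} exceeds the {len(ranked_markers)} available ranked markers"
        )
    root = np.random.SeedSequence(config.seed)
    repeat_seeds = root.generate_state(3 * config.n_repeats) >> 1

    rows = {k: [] for k in ks}
    oof: dict[int, list] = {k: [] for k in ks}
    for r in range(config.n_repeats):
        outer = make_stratified_folds(y, config.outer_folds, int(repeat_seeds[3 * r]))
        for f in range(config.outer_folds):
            te = outer == f
            tr = ~te
            if ranking == "refit":
                fold_markers = _fold_ranking(
                    expression.iloc[:, np.nonzero(tr)[0]], y[tr], ks[-1],
                    refit_voting, int(repeat_seeds[3 * r + 2]) + f,
                )
            else:
                fold_markers = ranked_markers[: ks[-1]]
            Zraw = expression.loc[fold_markers].to_numpy().T  # samples x maxK
            center = Zraw[tr].mean(axis=0)
            scale = Zraw[tr].std(axis=0)
            scale = np.where(scale < 1e-12, 1.0, scale)
            Z = (Zraw - center) / scale
            D2_by_k = _pairwise_sq_cumulative(Z, ks)
            tr_idx = np.nonzero(tr)[0]
            te_idx = np.nonzero(te)[0]
            inner_seed = int(repeat_seeds[3 * r + 1]) + f
            for k in ks:
                D2 = D2_by_k[k]
                gamma, cost, cv_dec = inner_grid_search(
                    D2[np.ix_(tr_idx, tr_idx)], y[tr], grid, config.inner_folds,
                    inner_seed,
                )
                a, b = platt_fit(cv_dec, y[tr])
                K_tr = np.exp(-gamma * D2[np.ix_(tr_idx, tr_idx)])
                K_te = np.exp(-gamma * D2[np.ix_(te_idx, tr_idx)])
                probs = platt_apply(_svm_decision(K_tr, y[tr], K_te, cost), a, b)
                auc = roc_auc(probs, y[te])
                sens, spec = sensitivity_specificity(probs, y[te], config.threshold)
                rows[k].append((auc, sens, spec))
                oof[k].append(pd.DataFrame(
                    {"probability": probs, "label": y[te], "repeat": r},
                    index=expression.columns[te_idx],
                ))

    summary = pd.DataFrame(index=pd.Index(ks, name="K"))
    for k in ks:
        arr = np.asarray(rows[k], dtype=float)
        acc = (arr[:, 1] + arr[:, 2]) / 2.0
        summary.loc[k, "mean_auc"] = arr[:, 0].mean()
        summary.loc[k, "sd_auc"] = arr[:, 0].std(ddof=1)
        summary.loc[k, "mean_sensitivity"] = arr[:, 1].mean()
        summary.loc[k, "mean_specificity"] = arr[:, 2].mean()
        summary.loc[k, "mean_accuracy"] = acc.mean()
    oof_frames = {k: pd.concat(v) for k, v in oof.items()}
    return summary, oof_frames


def _fold_ranking(expression, y, max_k, voting_config, seed):
    """Leakage-free marker ranking inside one outer-training part.

    Stability voting on the fold's training samples; if fewer than
    ``max_k`` markers are ever selected, the remainder is padded by
    univariate AUC computed on the same samples.
    """
    import dataclasses

    from .diffexpr import marker_auc
    from .voting import run_voting

    cfg = dataclasses.replace(voting_config, seed=seed)
    table, _ = run_voting(expression, y, cfg)
    ranked = list(table.sort_values("rank").index) if len(table) else []
    if len(ranked) < max_k:
        rest = [fid for fid in expression.index if fid not in set(ranked)]
        aucs = {fid: marker_auc(expression.loc[fid].to_numpy(), y)[0] for fid in rest}
        rest.sort(key=lambda fid: (-aucs[fid], fid))
        ranked += rest[: max_k - len(ranked)]
    return ranked[:max_k]


def choose_k(summary: pd.DataFrame, epsilon: float = 0.005) -> int:
    """Smallest K whose mean AUC is within ``epsilon`` of the best."""
    if summary.empty:
        raise ValueError("empty performance summary")
    best = summary["mean_auc"].max()
    ok = summary.index[summary["mean_auc"] >= best - epsilon]
    return int(ok.min())


def choose_threshold(
    probabilities: np.ndarray,
    labels01: np.ndarray,
    candidates: tuple[float, ...] = DEFAULT_THRESHOLD_CANDIDATES,
) -> float:
    """Candidate cutoff maximizing balanced accuracy.

    Ties resolve to the candidate nearest 0.5, then the smaller one.
    """
    scores = []
    for t in candidates:
        sens, spec = sensitivity_specificity(probabilities, labels01, t)
        scores.append((sens + spec) / 2.0)
    best = max(scores)
    tied = [t for t, s in zip(candidates, scores) if s >= best - 1e-12]
    return min(tied, key=lambda t: (abs(t - 0.5), t))


# ---------------------------------------------------------------------------
# final model


@dataclass
class DiagnosticModel:
    """Final K-marker RBF-SVM with Platt calibration, self-contained.

    Stores support vectors, dual coefficients and standardization
    parameters directly, so prediction is a plain numpy computation and
    the model serializes to JSON exactly.
    """

    marker_ids: list[str]
    gamma: float
    cost: float
    center: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray   # standardized, n_sv x K
    dual_coef: np.ndarray         # signed alphas, length n_sv
    intercept: float
    platt_a: float
    platt_b: float
    threshold: float = 0.55
    training_sample_ids: list[str] = field(default_factory=list)

    def _standardize(self, expression: pd.DataFrame) -> np.ndarray:
        missing = [m for m in self.marker_ids if m not in expression.index]
        if missing:
            raise ValueError(f"markers missing from expression matrix: {missing[:5]}")
        Z = expression.loc[self.marker_ids].to_numpy().T
        return (Z - self.center) / self.scale

    def decision_function(self, expression: pd.DataFrame) -> np.ndarray:
        Z = self._standardize(expression)
        d2 = (
            (Z * Z).sum(axis=1)[:, None]
            + (self.support_vectors * self.support_vectors).sum(axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict_proba(self, expression: pd.DataFrame) -> np.ndarray:
        return platt_apply(self.decision_function(expression), self.platt_a, self.platt_b)

    def predict(self, expression: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(expression) > self.threshold).astype(int)

    def to_json(self) -> str:
        d = {
            "marker_ids": self.marker_ids,
            "gamma": self.gamma,
            "cost": self.cost,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "threshold": self.threshold,
            "training_sample_ids": self.training_sample_ids,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticModel":
        d = json.loads(text)
        for key in ("center", "scale", "support_vectors", "dual_coef"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def fit_final(
    expression: pd.DataFrame,
    labels: np.ndarray,
    marker_ids: list[str],
    gamma: float,
    cost: float,
    threshold: float = 0.55,
    calibration_folds: int = 5,
    seed: int = 0,
) -> DiagnosticModel:
    """Fit the final RBF-SVM on the whole training cohort.

    Marker rows are standardized with full-training statistics; the Platt
    sigmoid is fitted on ``calibration_folds``-fold cross-validated
    decision values (refitting the SVM per fold), not on resubstitution
    values, which would be optimistic.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    missing = [m for m in marker_ids if m not in expression.index]
    if missing:
        raise ValueError(f"markers missing from expression matrix: {missing[:5]}")
    Zraw = expression.loc[marker_ids].to_numpy().T
    center = Zraw.mean(axis=0)
    scale = Zraw.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    Z = (Zraw - center) / scale

    folds = make_stratified_folds(y, calibration_folds, seed)
    cv_dec = np.zeros(len(y))
    for f in range(calibration_folds):
        te = folds == f
        svc = SVC(kernel="rbf", gamma=gamma, C=cost)
        svc.fit(Z[~te], y[~te])
        cv_dec[te] = svc.decision_function(Z[te])
    a, b = platt_fit(cv_dec, y)

    svc = SVC(kernel="rbf", gamma=gamma, C=cost)
    svc.fit(Z, y)
    return DiagnosticModel(
        marker_ids=list(marker_ids),
        gamma=float(gamma),
        cost=float(cost),
        center=center,
        scale=scale,
        support_vectors=Z[svc.support_],
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        platt_a=a,
        platt_b=b,
        threshold=float(threshold),
        training_sample_ids=list(expression.columns),
    )


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    confusion: dict[str, int]
    probabilities: pd.Series
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    band_fpr: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    threshold: float
    comparator: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion,
            "threshold": self.threshold,
            "probabilities": {k: float(v) for k, v in self.probabilities.items()},
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()},
            "band": {
                "fpr": self.band_fpr.tolist(),
                "lower": self.band_lower.tolist(),
                "upper": self.band_upper.tolist(),
            },
        }
        if self.comparator is not None:
            d["comparator"] = self.comparator
        return d


def _roc_with_band(
    scores: np.ndarray,
    y: np.ndarray,
    n_boot: int,
    level: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, tuple[float, float]]:
    """ROC curve plus a stratified percentile-bootstrap pointwise band."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    grid = np.linspace(0.0, 1.0, 101)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    tprs = np.empty((n_boot, len(grid)))
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        fb, tb, _ = roc_curve(y[idx], scores[idx])
        tprs[b] = np.interp(grid, fb, tb)
        aucs[b] = roc_auc(scores[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(tprs, alpha, axis=0)
    upper = np.quantile(tprs, 1.0 - alpha, axis=0)
    auc_ci = (float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1.0 - alpha)))
    return fpr, tpr, grid, lower, upper, auc_ci


def validate(
    model: DiagnosticModel,
    val_expression: pd.DataFrame,
    val_labels: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> ValidationReport:
    """Score an external validation cohort.

    Validation sample ids must be disjoint from the model's training ids
    (leakage guard).  Sensitivity/specificity use the model's stored
    probability threshold; the ROC band is a stratified percentile
    bootstrap.
    """
    overlap = set(val_expression.columns) & set(model.training_sample_ids)
    if overlap:
        raise ValueError(
            f"validation samples overlap the training cohort: {sorted(overlap)[:5]}"
        )
    y = np.asarray(val_labels, dtype=int)
    probs = model.predict_proba(val_expression)
    call = probs > model.threshold
    sens, spec = sensitivity_specificity(probs, y, model.threshold)
    if np.isnan(sens) or np.isnan(spec):
        warnings.warn("one class absent from the validation cohort; the "
                      "corresponding rate is reported as NaN")
    if len(np.unique(y)) == 2:
        auc = roc_auc(probs, y)
        fpr, tpr, bfpr, lo, hi, auc_ci = _roc_with_band(probs, y, n_boot, level, seed)
    else:
        auc, auc_ci = float("nan"), (float("nan"), float("nan"))
        fpr = tpr = bfpr = lo = hi = np.array([])
    confusion = {
        "tp": int((call & (y == 1)).sum()),
        "fn": int((~call & (y == 1)).sum()),
        "fp": int((call & (y == 0)).sum()),
        "tn": int((~call & (y == 0)).sum()),
    }
    return ValidationReport(
        auc=auc,
        auc_ci=auc_ci,
        sensitivity=sens,
        specificity=spec,
        confusion=confusion,
        probabilities=pd.Series(probs, index=val_expression.columns),
        roc_fpr=fpr,
        roc_tpr=tpr,
        band_fpr=bfpr,
        band_lower=lo,
        band_upper=hi,
        threshold=model.threshold,
    )


@dataclass(frozen=True)
class ComparatorSpec:
    """Scalar-biomarker cutoff rule (e.g. serum CA19-9 > 37 U/mL)."""

    value_name: str = "CA19-9"
    cutoff: float = 37.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def comparator_diagnosis(
    values: np.ndarray,
    labels01: np.ndarray,
    spec: ComparatorSpec = ComparatorSpec(),
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Diagnose by ``value > cutoff``; AUC from the raw continuous value.

    Missing values count as negative calls and are excluded from the AUC;
    their count is reported.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels01, dtype=int)
    present = np.isfinite(v)
    call = present & (v > spec.cutoff)
    with np.errstate(invalid="ignore"):
        sens = float(call[y == 1].mean()) if (y == 1).any() else float("nan")
        spec_ = float((~call[y == 0]).mean()) if (y == 0).any() else float("nan")
    block: dict = {
        "value_name": spec.value_name,
        "cutoff": spec.cutoff,
        "sensitivity": sens,
        "specificity": spec_,
        "n_missing": int((~present).sum()),
        "confusion": {
            "tp": int((call & (y == 1)).sum()),
            "fn": int((~call & (y == 1)).sum()),
            "fp": int((call & (y == 0)).sum()),
            "tn": int((~call & (y == 0)).sum()),
        },
    }
    if len(np.unique(y[present])) == 2:
        block["auc"] = roc_auc(v[present], y[present])
        _, _, bfpr, lo, hi, auc_ci = _roc_with_band(
            v[present], y[present], n_boot, level, seed
        )
        block["auc_ci"] = list(auc_ci)
        block["band"] = {"fpr": bfpr.tolist(), "lower": lo.tolist(), "upper": hi.tolist()}
    else:
        block["auc"] = float("nan")
    return block
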