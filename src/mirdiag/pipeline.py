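"""End-to-end biomarker discovery and diagnosis workflow.

Ties the stages together on a training + validation cohort: differential
expression under two control definitions, stability voting, double
cross-validation over panel sizes, probability-threshold selection, final
RBF-SVM fit, external validation with a scalar-comparator reference, and
PCA projections with confidence ellipses.  Every run writes its artifacts
(TSV tables, JSON reports, a reproducibility manifest) into an output
directory; all randomness flows from one root seed through named
substreams, so identical configurations produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnosis import (
    ComparatorSpec,
    DoubleCVConfig,
    GridSpec,
    choose_k,
    choose_threshold,
    comparator_diagnosis,
    double_cv,
    fit_final,
    inner_grid_search,
    sensitivity_specificity,
    validate,
    _pairwise_sq_cumulative,
)
from .diffexpr import DEAConfig, differential_expression, select_demirnas, venn_partition
from .io import (
    PC_VS_NONCANCER,
    PC_VS_NONPC,
    GroupingRule,
    align_and_group,
    read_expression,
    read_metadata,
)
from .pca import confidence_ellipse, fit_pca, project
from .voting import VotingConfig, run_voting, top_k

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression_path: str = ""
    metadata_path: str = ""
    output_dir: str = "mirdiag_out"
    grouping: GroupingRule = PC_VS_NONPC
    secondary_grouping: GroupingRule = PC_VS_NONCANCER
    dea: DEAConfig = field(default_factory=DEAConfig)
    voting: VotingConfig = field(default_factory=VotingConfig)
    double_cv: DoubleCVConfig = field(default_factory=DoubleCVConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    comparator: ComparatorSpec = field(default_factory=ComparatorSpec)
    seed: int = 0
    k_override: int | None = None
    threshold_override: float | None = None
    log_level: str = "INFO"

    def resolved(self) -> "RunConfig":
        """Propagate the root seed into per-stage seeds via substreams."""
        import dataclasses

        children = np.random.SeedSequence(self.seed).generate_state(4) >> 1
        return dataclasses.replace(
            self,
            voting=dataclasses.replace(self.voting, seed=int(children[0])),
            double_cv=dataclasses.replace(self.double_cv, seed=int(children[1])),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration (where outputs go is excluded)."""
    d = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    text = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    expression: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Execute the full workflow and write all artifacts.

    Inputs may be passed in memory (``expression``, ``metadata``) or read
    from the configured paths.  Returns the report bundle: selected
    markers, chosen K and threshold, performance summary, validation
    report, Venn partition, PCA artifacts and the output paths.
    """
    logging.basicConfig(level=config.log_level)
    config = config.resolved()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": _config_hash(config), "seed": config.seed}

    if expression is None:
        expression = read_expression(config.expression_path)
    if metadata is None:
        metadata = read_metadata(config.metadata_path)

    seeds = np.random.SeedSequence(config.seed).generate_state(8) >> 1
    final_seed, boot_seed, grid_seed = int(seeds[4]), int(seeds[5]), int(seeds[6])

    def _stage(name):
        logger.info("stage: %s", name)

    # ---- grouping -----------------------------------------------------
    _stage("align_and_group")
    X_all, y_all, meta_all = align_and_group(expression, metadata, config.grouping)
    train = (meta_all["cohort"] == "training").to_numpy()
    val = (meta_all["cohort"] == "validation").to_numpy()
    X_tr = X_all.iloc[:, train.nonzero()[0]]
    y_tr = y_all[train]
    X_va = X_all.iloc[:, val.nonzero()[0]]
    y_va = y_all[val]
    meta_tr = meta_all[train].reset_index(drop=True)
    meta_va = meta_all[val].reset_index(drop=True)

    # ---- differential expression (two control definitions) ------------
    _stage("differential_expression")
    de_primary = differential_expression(X_tr, y_tr, config.dea)
    de_primary.to_csv(out / "de_primary.tsv", sep="\t")
    set_primary = select_demirnas(de_primary, config.dea)

    X2, y2, meta2 = align_and_group(expression, metadata, config.secondary_grouping)
    train2 = (meta2["cohort"] == "training").to_numpy()
    de_secondary = differential_expression(X2.iloc[:, train2.nonzero()[0]], y2[train2], config.dea)
    de_secondary.to_csv(out / "de_secondary.tsv", sep="\t")
    set_secondary = select_demirnas(de_secondary, config.dea)

    # ---- stability voting ---------------------------------------------
    _stage("marker_voting")
    freq_table, provenance = run_voting(X_tr, y_tr, config.voting)
    freq_table.to_csv(out / "marker_frequency.tsv", sep="\t")
    with open(out / "candidate_sets.jsonl", "w") as fh:
        for cs in provenance:
            fh.write(json.dumps({
                "repeat": cs.repeat_index,
                "fold": cs.fold_index,
                "features": sorted(cs.feature_ids),
            }) + "\n")
    ranked = list(freq_table.sort_values("rank").index)
    if not ranked:
        raise RuntimeError("voting selected no features; cannot build a panel")

    # ---- double cross-validation over K --------------------------------
    _stage("double_cv")
    ks = tuple(k for k in config.double_cv.k_range if k <= len(ranked))
    if not ks:
        raise RuntimeError(
            f"no K in {config.double_cv.k_range} is within the {len(ranked)} ranked markers"
        )
    import dataclasses

    dcv_config = dataclasses.replace(config.double_cv, k_range=ks)
    summary, oof = double_cv(X_tr, y_tr, ranked, dcv_config, config.grid)
    summary.to_csv(out / "performance_by_k.tsv", sep="\t")

    k_star = config.k_override if config.k_override is not None else choose_k(summary)
    _stage(f"choose_threshold (K={k_star})")
    pooled = oof[k_star]
    if config.threshold_override is not None:
        threshold = config.threshold_override
    else:
        threshold = choose_threshold(
            pooled["probability"].to_numpy(),
            pooled["label"].to_numpy(),
            config.double_cv.candidate_thresholds,
        )
    cv_sens, cv_spec = sensitivity_specificity(
        pooled["probability"].to_numpy(), pooled["label"].to_numpy(), threshold
    )

    # ---- final model ----------------------------------------------------
    _stage("fit_final")
    panel = top_k(freq_table, k_star)
    Zraw = X_tr.loc[panel].to_numpy().T
    center = Zraw.mean(axis=0)
    scale = np.where(Zraw.std(axis=0) < 1e-12, 1.0, Zraw.std(axis=0))
    D2 = _pairwise_sq_cumulative((Zraw - center) / scale, [len(panel)])[len(panel)]
    gamma, cost, _ = inner_grid_search(
        D2, y_tr, config.grid, config.double_cv.inner_folds, grid_seed
    )
    model = fit_final(X_tr, y_tr, panel, gamma, cost, threshold=threshold, seed=final_seed)
    (out / "model.json").write_text(model.to_json())

    # ---- Venn partition of the panel ------------------------------------
    in_both, only_primary, venn_flags = venn_partition(
        set(set_secondary), set(set_primary), panel
    )
    venn_flags.to_csv(out / "panel_venn.tsv", sep="\t")

    # ---- external validation -------------------------------------------
    _stage("validate")
    report = validate(model, X_va, y_va, seed=boot_seed)
    comp_values = meta_va["comparator_value"].to_numpy(dtype=float)
    if np.isfinite(comp_values).any():
        report.comparator = comparator_diagnosis(
            comp_values, y_va, config.comparator, seed=boot_seed
        )
    (out / "validation_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    roc = pd.DataFrame({"fpr": report.band_fpr, "tpr_lower": report.band_lower,
                        "tpr_upper": report.band_upper})
    roc.to_csv(out / "roc_band.tsv", sep="\t", index=False)

    # ---- PCA views ------------------------------------------------------
    _stage("pca")
    pca_artifacts = {}
    for tag, subset in (("all", None), ("de", set_primary or None)):
        if subset is None and tag == "de":
            continue
        pca_model = fit_pca(X_tr, feature_subset=subset, n_components=2)
        scores_tr = project(pca_model, X_tr)
        scores_va = project(pca_model, X_va)
        scores = pd.concat([
            scores_tr.assign(group=np.where(y_tr == 1, "case", "control"), cohort="training"),
            scores_va.assign(group=np.where(y_va == 1, "case", "control"), cohort="validation"),
        ])
        scores.to_csv(out / f"pca_scores_{tag}.tsv", sep="\t", index_label="sample_id")
        ellipses = {}
        for grp in ("case", "control"):
            pts = scores_tr[np.asarray(y_tr == (1 if grp == "case" else 0))].to_numpy()
            if len(pts) >= 4:
                e = confidence_ellipse(pts, level=0.95, group=grp)
                ellipses[grp] = {
                    "center": e.center.tolist(),
                    "shape": e.shape.tolist(),
                    "level": e.level,
                    "df": e.df,
                }
        (out / f"pca_ellipses_{tag}.json").write_text(json.dumps(ellipses, indent=1))
        pca_artifacts[tag] = {
            "explained_variance_ratio": pca_model.explained_variance_ratio[:2].tolist(),
            "ellipses": ellipses,
        }

    # ---- report bundle ---------------------------------------------------
    bundle = {
        **stamp,
        "n_training": int(train.sum()),
        "n_validation": int(val.sum()),
        "n_de_primary": len(set_primary),
        "n_de_secondary": len(set_secondary),
        "panel": panel,
        "chosen_k": int(k_star),
        "threshold": float(threshold),
        "gamma": float(gamma),
        "cost": float(cost),
        "cv_mean_auc_at_k": float(summary.loc[k_star, "mean_auc"]),
        "cv_sensitivity_at_threshold": float(cv_sens),
        "cv_specificity_at_threshold": float(cv_spec),
        "venn": {"in_both": in_both, "only_primary_grouping": only_primary},
        "validation": {
            "auc": report.auc,
            "auc_ci": list(report.auc_ci),
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "comparator": report.comparator,
        },
        "pca": pca_artifacts,
        "chance_level": bool(summary["mean_auc"].max() < 0.6),
        "output_dir": str(out),
    }
    manifest = {
        **stamp,
        "config": config.to_dict(),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "report.json").write_text(json.dumps(bundle, indent=1, default=str))
    return bundle


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "mirdiag": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scipy": scipy.__version__,
    }
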