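"""Seeded synthetic case-control expression cohorts with known ground truth.

The generator emulates a serum miRNA microarray case-control study on the
log2 scale: a features x samples matrix of normalized log2 intensities, a
per-sample metadata table (case/control label, disease subgroup, training or
validation cohort, optional scalar comparator biomarker such as CA19-9 in
U/mL), and the set of truly informative features.

The generative law is Gaussian on the log2 scale: every feature has a
baseline mean and a per-feature noise standard deviation; informative
features receive an additive mean shift in case samples.  Noise may be
equicorrelated within contiguous feature blocks to stress selectors with
redundant features.  Training and validation samples are drawn from the same
law, except that validation controls (the hard, tumor-bearing control
analogue) may optionally receive a configurable fraction of the case shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_comparator",
    "TRAINING_CONTROL_COMPOSITION",
]

#: Default disease-subgroup composition of the training control arm
#: (tumor-bearing non-case cancers plus benign/healthy subjects), as counts
#: out of 63.  Scaled proportionally for other control-arm sizes.
TRAINING_CONTROL_COMPOSITION: dict[str, int] = {
    "ICC": 20,
    "SC": 7,
    "CRC": 5,
    "GIST": 2,
    "Ch": 10,
    "N": 19,
}

CASE_SUBGROUP = "PC"
VALIDATION_CONTROL_SUBGROUP = "ICC"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic case-control cohort.

    Defaults mirror the emulated study design: 2578 mature-miRNA features, a 63
    case / 63 control training cohort, a 25 case / 81 control validation
    cohort and unit log2-scale noise.  The informative subset is supplied
    per scenario; strongly differential serum markers typically carry
    signed log2 shifts of 1.5-2 noise SDs.
    """

    n_case: int = 63
    n_control: int = 63
    n_val_case: int = 25
    n_val_control: int = 81
    p: int = 2578
    informative_ids: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = ()
    baseline_means: np.ndarray | float = 7.0
    noise_sd: np.ndarray | float = 1.0
    block_correlation: float = 0.0
    block_size: int = 1
    val_control_shift_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_val_case < 0 or self.n_val_control < 0:
            raise ValueError("validation counts must be non-negative")
        ids = tuple(int(i) for i in self.informative_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("informative_ids must be distinct")
        if len(ids) > self.p:
            raise ValueError(f"number of informative features {len(ids)} exceeds p={self.p}")
        if any(i < 0 or i >= self.p for i in ids):
            raise ValueError("informative indices must lie in [0, p)")
        if len(self.effect_sizes) != len(ids):
            raise ValueError("effect_sizes must match informative_ids in length")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError(f"block_correlation must lie in [0, 1), got {self.block_correlation}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (self.p,))
        if not np.all(sd > 0):
            raise ValueError("noise_sd must be strictly positive for every feature")
        object.__setattr__(self, "informative_ids", ids)
        object.__setattr__(self, "effect_sizes", tuple(float(e) for e in self.effect_sizes))

    @property
    def n_informative(self) -> int:
        return len(self.informative_ids)

    def with_effects(self, ids: Sequence[int], effects: Sequence[float]) -> "CohortSpec":
        return replace(self, informative_ids=tuple(ids), effect_sizes=tuple(effects))


def _control_subgroups(n_control: int, rng: np.random.Generator) -> list[str]:
    """Assign training-control subgroups proportionally to the default mix."""
    total = sum(TRAINING_CONTROL_COMPOSITION.values())
    labels: list[str] = []
    for sub, count in TRAINING_CONTROL_COMPOSITION.items():
        labels.extend([sub] * int(round(count * n_control / total)))
    # rounding can over/undershoot; trim or pad with the largest subgroup
    while len(labels) > n_control:
        labels.pop()
    while len(labels) < n_control:
        labels.append("N")
    rng.shuffle(labels)
    return labels


def _draw_noise(rng: np.random.Generator, p: int, n: int, sd: np.ndarray,
                rho: float, block_size: int) -> np.ndarray:
    """Correlated Gaussian noise, equicorrelated within contiguous blocks."""
    if rho == 0.0 or block_size == 1:
        z = rng.standard_normal((p, n))
    else:
        n_blocks = -(-p // block_size)
        shared = rng.standard_normal((n_blocks, n))
        idio = rng.standard_normal((p, n))
        block_of = np.arange(p) // block_size
        z = np.sqrt(rho) * shared[block_of] + np.sqrt(1.0 - rho) * idio
    return z * sd[:, None]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Generate a synthetic cohort.

    Returns
    -------
    expression : pandas.DataFrame
        Log2 intensities, features x samples.  ``value[j, i] =
        baseline[j] + effect[j] * 1(i is case, j informative) + noise``.
    metadata : pandas.DataFrame
        Columns ``sample_id, label, subgroup, cohort, comparator_value``
        (comparator left missing; see :func:`generate_comparator`).
    truth : set of str
        Feature ids of the truly informative features.  Returned out of
        band and never written into the expression table, so the pipeline
        under test cannot see it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    p = spec.p
    baseline = np.broadcast_to(np.asarray(spec.baseline_means, dtype=float), (p,)).copy()
    sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (p,)).copy()

    effect = np.zeros(p)
    if spec.informative_ids:
        effect[list(spec.informative_ids)] = spec.effect_sizes

    arms = [
        ("case", "training", spec.n_case, effect),
        ("control", "training", spec.n_control, None),
        ("case", "validation", spec.n_val_case, effect),
        ("control", "validation", spec.n_val_control,
         effect * spec.val_control_shift_fraction),
    ]

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    counter = 0
    for label, cohort, n, shift in arms:
        if n == 0:
            continue
        noise = _draw_noise(rng, p, n, sd, spec.block_correlation, spec.block_size)
        mean = baseline if shift is None else baseline + shift
        blocks.append(mean[:, None] + noise)
        if label == "control" and cohort == "training":
            subgroups = _control_subgroups(n, rng)
        elif label == "control":
            subgroups = [VALIDATION_CONTROL_SUBGROUP] * n
        else:
            subgroups = [CASE_SUBGROUP] * n
        for k in range(n):
            meta_rows.append({
                "sample_id": f"S{counter:04d}",
                "label": label,
                "subgroup": subgroups[k],
                "cohort": cohort,
                "comparator_value": np.nan,
            })
            counter += 1

    values = np.concatenate(blocks, axis=1)
    feature_ids = [f"miR-{j:04d}" for j in range(p)]
    sample_ids = [row["sample_id"] for row in meta_rows]
    expression = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                              columns=sample_ids)
    metadata = pd.DataFrame(meta_rows)
    truth = {feature_ids[j] for j in spec.informative_ids}
    return expression, metadata, truth


def generate_comparator(
    metadata: pd.DataFrame,
    case_lognormal_params: tuple[float, float],
    control_lognormal_params: tuple[float, float],
    seed: int,
) -> pd.DataFrame:
    """Fill ``comparator_value`` with log-normal draws per label.

    Parameters are ``(median, sigma)`` of the log-normal on the natural
    scale: a value is ``median * exp(sigma * Z)`` with ``Z`` standard
    normal, so the distribution median equals ``median`` exactly and
    ``sigma`` is the log-scale standard deviation.  ``sigma = 0`` gives a
    degenerate (point-mass) distribution, useful for exact separation
    checks.  Emulates a serum tumor-marker assay such as CA19-9 (U/mL).
    """
    for name, (median, sigma) in (("case", case_lognormal_params),
                                  ("control", control_lognormal_params)):
        if median <= 0:
            raise ValueError(f"{name} log-normal median must be positive, got {median}")
        if sigma < 0:
            raise ValueError(f"{name} log-normal sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = metadata.copy()
    values = np.empty(len(out))
    for name, (median, sigma) in (("case", case_lognormal_params),
                                  ("control", control_lognormal_params)):
        mask = (out["label"] == name).to_numpy()
        values[mask] = median * np.exp(sigma * rng.standard_normal(mask.sum()))
    out["comparator_value"] = values
    return out
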