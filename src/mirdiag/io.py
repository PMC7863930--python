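"""Readers, writers and cohort-grouping rules.

All tabular artifacts are tab-separated text: the expression matrix has
features as rows (first column = feature id, header = sample ids), and the
metadata table has one row per sample (``sample_id, label, subgroup,
cohort, comparator_value``).  Structured reports are JSON.  Case/control
grouping is an explicit rule mapping disease subgroups to case, control or
excluded — the same matrix supports multiple control definitions (e.g.
case vs all non-case, case vs non-cancer only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroupingRule",
    "PC_VS_NONPC",
    "PC_VS_NONCANCER",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "align_and_group",
    "load_config",
]

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "label", "subgroup", "cohort", "comparator_value"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a features x samples expression TSV, validating shape and values."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    bad_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad_cols:
        col = bad_cols[0]
        row = df[pd.to_numeric(df[col], errors="coerce").isna()].index
        raise ValueError(
            f"{path}: non-numeric value in column {col!r}"
            + (f" at feature {row[0]!r}" if len(row) else "")
        )
    if df.isna().any().any():
        feat = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value at feature {feat!r}")
    # heuristic: array panels have far more features than samples; a wide,
    # very short table is almost certainly transposed
    if df.shape[0] * 10 < df.shape[1] and df.shape[0] < 30:
        raise ValueError(
            f"{path}: {df.shape[0]} features x {df.shape[1]} samples looks transposed "
            "(expected features as rows); transpose the file rather than the reader"
        )
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if "comparator_value" not in df.columns:
        df["comparator_value"] = np.nan
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    bad = set(df["label"]) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: invalid label values {sorted(bad)}")
    bad = set(df["cohort"]) - {"training", "validation"}
    if bad:
        raise ValueError(f"{path}: invalid cohort values {sorted(bad)}")
    return df[METADATA_COLUMNS].copy()


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GroupingRule:
    """Maps disease subgroups to case/control; others are excluded."""

    name: str
    case_subgroups: tuple[str, ...]
    control_subgroups: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.case_subgroups) & set(self.control_subgroups)
        if overlap:
            raise ValueError(f"subgroups assigned to both arms: {sorted(overlap)}")


#: Case vs every non-case sample (other cancers and non-cancer controls).
PC_VS_NONPC = GroupingRule("PC_vs_nonPC", ("PC",), ("ICC", "SC", "CRC", "GIST", "Ch", "N"))
#: Case vs non-cancer controls only (healthy and benign disease).
PC_VS_NONCANCER = GroupingRule("PC_vs_noncancer", ("PC",), ("Ch", "N"))


def align_and_group(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    rule: GroupingRule,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Align matrix columns to metadata and derive labels from the rule.

    Returns ``(X, y, meta)`` where ``X`` holds only the samples the rule
    assigns (columns in metadata order), ``y`` is 1 for case and 0 for
    control, and ``meta`` is the matching metadata slice (carrying cohort
    and comparator columns).  Samples in neither arm are excluded with a
    logged count; a metadata sample missing from the matrix is an error.
    """
    missing = [s for s in metadata["sample_id"] if s not in expression.columns]
    if missing:
        raise ValueError(f"metadata samples absent from expression matrix: {missing[:5]}")
    in_case = metadata["subgroup"].isin(rule.case_subgroups)
    in_control = metadata["subgroup"].isin(rule.control_subgroups)
    keep = in_case | in_control
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("grouping %s: excluded %d samples in neither arm", rule.name, n_excluded)
    meta = metadata[keep].reset_index(drop=True)
    X = expression[meta["sample_id"].tolist()]
    y = meta["subgroup"].isin(rule.case_subgroups).astype(int).to_numpy()
    return X, y, meta


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data
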