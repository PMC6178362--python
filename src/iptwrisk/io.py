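"""Cohort CSV reading/writing and pipeline configuration.

The cohort file is UTF-8, comma-separated, one row per participant, with
lower_snake_case column names exactly matching the participant-record fields
(see :data:`iptwrisk.cohort.COHORT_COLUMNS`); missing values are empty cells;
booleans are ``True``/``False`` (``1``/``0`` accepted on input).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    COHORT_COLUMNS,
    ECONOMIC_LEVELS,
    MARITAL_LEVELS,
    SEX_LEVELS,
    CohortValidationError,
)

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "PipelineConfig",
]

logger = logging.getLogger(__name__)

_NUMERIC = ("age", "education_years", "bmi", "sbp1", "sbp2", "dbp1", "dbp2", "fbg", "hba1c")
_BOOLEAN = ("smoking", "glucose_meds", "bp_meds_or_dx", "followup_observed", "diabetes_followup")
_CATEGORICAL = {
    "sex": SEX_LEVELS,
    "marital_status": MARITAL_LEVELS,
    "economic_status": ECONOMIC_LEVELS,
}

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool_column(raw: pd.Series, col: str) -> pd.Series:
    out = pd.array([pd.NA] * len(raw), dtype="boolean")
    for i, v in enumerate(raw):
        if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
            continue
        s = str(v).strip().lower()
        if s in _TRUE:
            out[i] = True
        elif s in _FALSE:
            out[i] = False
        else:
            raise CohortValidationError(
                f"row {i}: cannot parse boolean cell {v!r} in column {col!r}"
            )
    return pd.Series(out, index=raw.index)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV into a typed DataFrame.

    Checks for required columns, duplicate ids, unparseable numeric cells,
    unknown categorical levels, and consistency of the follow-up fields
    (``diabetes_followup`` present iff ``followup_observed``). Per-column
    missingness is logged.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    missing_cols = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortValidationError(f"missing required column(s): {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    df["id"] = raw["id"].astype(str)
    df["cluster_id"] = raw["cluster_id"].astype(str)
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise CohortValidationError(f"duplicate id(s): {sorted(dup.unique())[:5]}")

    for col in _NUMERIC:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            i = int(bad.idxmax())
            raise CohortValidationError(
                f"row {i}: cannot parse numeric cell {raw.loc[i, col]!r} in column {col!r}"
            )
        df[col] = parsed

    for col, levels in _CATEGORICAL.items():
        vals = raw[col]
        bad = vals.notna() & ~vals.isin(levels)
        if bad.any():
            i = int(bad.idxmax())
            raise CohortValidationError(
                f"row {i}: invalid level {vals[i]!r} in column {col!r} "
                f"(expected one of {list(levels)})"
            )
        df[col] = vals

    for col in _BOOLEAN:
        df[col] = _parse_bool_column(raw[col], col)

    obs = df["followup_observed"]
    inconsistent = (obs.fillna(False) & df["diabetes_followup"].isna()) | (
        ~obs.fillna(True) & df["diabetes_followup"].notna()
    )
    if inconsistent.any():
        i = int(inconsistent.idxmax())
        raise CohortValidationError(
            f"row {i} (id {df.loc[i, 'id']}): diabetes_followup must be present "
            "iff followup_observed is true"
        )

    n_missing = df.isna().sum()
    for col, cnt in n_missing[n_missing > 0].items():
        logger.info("column %s: %d missing values", col, cnt)
    logger.info("read %d cohort records from %s", len(df), path)
    return df[list(COHORT_COLUMNS)]


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort DataFrame in the standard CSV dialect."""
    cohort.to_csv(path, index=False, na_rep="")


@dataclass
class PipelineConfig:
    """End-to-end analysis configuration (serializable to YAML)."""

    input_path: str = ""
    scheme: str = "jnc7"
    interaction: bool = True
    truncation: tuple[float, float] | None = None
    ci_method: str = "sandwich"
    bootstrap_reps: int = 999
    seed: int | None = None
    clip: float = 1e-6
    censor_numerator: str = "marginal"
    output_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.scheme not in ("jnc7", "jnc6"):
            raise ValueError(f"scheme must be jnc7 or jnc6, got {self.scheme!r}")
        if self.ci_method not in ("sandwich", "cluster-bootstrap"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        if self.ci_method == "cluster-bootstrap" and self.seed is None:
            raise ValueError("cluster-bootstrap requires a seed")
        if self.censor_numerator not in ("marginal", "exposure"):
            raise ValueError(f"unknown censor_numerator {self.censor_numerator!r}")
        if self.truncation is not None:
            self.truncation = tuple(float(x) for x in self.truncation)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if d["truncation"] is not None:
            d["truncation"] = list(d["truncation"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)
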