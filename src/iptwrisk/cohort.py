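"""Cohort domain model: participant records, blood-pressure classification,
diabetes status, and baseline eligibility.

The analysis cohort is a :class:`pandas.DataFrame` with one row per participant
(columns listed in :data:`COHORT_COLUMNS`); :class:`ParticipantRecord` is the
typed single-row view used for validation. Blood pressure is classified under
two guideline schemes simultaneously:

* JNC-7: normal (<120/<80), pre-hypertension (120–139 and/or 80–89),
  hypertension (>=140 and/or >=90).
* JNC-6: optimal (<120/<80), normal (120–129 and/or 80–84), high-normal
  (130–139 and/or 85–89), hypertension as above. The 2017 ACC/AHA labels
  "elevated BP" and "stage 1 hypertension" are aliases of the JNC-6 normal and
  high-normal bands, respectively.

A pair of systolic/diastolic readings taken minutes apart is combined by
arithmetic mean before classification. Baseline diabetes is a fasting glucose
of at least 126 mg/dL, an HbA1c of at least 6.5%, or use of glucose-lowering
medication. Participants hypertensive or diabetic at baseline are ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_COLUMNS",
    "SEX_LEVELS",
    "MARITAL_LEVELS",
    "ECONOMIC_LEVELS",
    "JNC7_LEVELS",
    "JNC6_LEVELS",
    "ACC_ALIASES",
    "CohortValidationError",
    "IndeterminateStatusError",
    "ParticipantRecord",
    "BPCategory",
    "EligibilityReport",
    "average_bp",
    "classify_bp",
    "diabetes_status",
    "apply_eligibility",
]

SEX_LEVELS = ("male", "female")
MARITAL_LEVELS = ("married", "other")
ECONOMIC_LEVELS = ("low", "medium", "high")

JNC7_LEVELS = ("normal", "prehypertension", "hypertension")
JNC6_LEVELS = ("optimal", "normal", "high_normal", "hypertension")

#: 2017 ACC/AHA names for the two JNC-6 sub-bands of JNC-7 pre-hypertension.
ACC_ALIASES = {"normal": "elevated", "high_normal": "stage1_hypertension"}

COHORT_COLUMNS = (
    "id",
    "cluster_id",
    "age",
    "sex",
    "marital_status",
    "education_years",
    "economic_status",
    "smoking",
    "bmi",
    "sbp1",
    "sbp2",
    "dbp1",
    "dbp2",
    "fbg",
    "hba1c",
    "glucose_meds",
    "bp_meds_or_dx",
    "followup_observed",
    "diabetes_followup",
)


class CohortValidationError(ValueError):
    """A participant record violates a structural invariant."""


class IndeterminateStatusError(ValueError):
    """Diabetes status cannot be determined (all glucose inputs missing)."""


@dataclass(frozen=True)
class BPCategory:
    """Blood-pressure category under both guideline schemes."""

    jnc7: str
    jnc6: str

    @property
    def acc(self) -> str:
        """ACC/AHA 2017 label (alias of the JNC-6 category)."""
        return ACC_ALIASES.get(self.jnc6, self.jnc6)


@dataclass
class ParticipantRecord:
    """One subject's baseline covariates, BP readings, labs and follow-up."""

    id: str
    cluster_id: str
    age: float
    sex: str
    marital_status: str
    education_years: float
    economic_status: str
    smoking: bool
    bmi: float
    sbp1: float
    sbp2: float
    dbp1: float
    dbp2: float
    fbg: float | None = None
    hba1c: float | None = None
    glucose_meds: bool = False
    bp_meds_or_dx: bool = False
    followup_observed: bool = True
    diabetes_followup: bool | None = None

    def validate(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise CohortValidationError(f"record {self.id}: invalid sex {self.sex!r}")
        if self.marital_status not in MARITAL_LEVELS:
            raise CohortValidationError(
                f"record {self.id}: invalid marital_status {self.marital_status!r}"
            )
        if self.economic_status not in ECONOMIC_LEVELS:
            raise CohortValidationError(
                f"record {self.id}: invalid economic_status {self.economic_status!r}"
            )
        if not self.bmi > 0:
            raise CohortValidationError(f"record {self.id}: bmi must be positive")
        if self.education_years < 0:
            raise CohortValidationError(
                f"record {self.id}: education_years must be non-negative"
            )
        for s, d, tag in ((self.sbp1, self.dbp1, "1"), (self.sbp2, self.dbp2, "2")):
            if not (s > 0 and d > 0):
                raise CohortValidationError(
                    f"record {self.id}: non-positive BP reading {tag}"
                )
            if not s > d:
                raise CohortValidationError(
                    f"record {self.id}: SBP must exceed DBP in reading {tag}"
                )
        if self.followup_observed and self.diabetes_followup is None:
            raise CohortValidationError(
                f"record {self.id}: followed-up record lacks diabetes_followup"
            )
        if not self.followup_observed and self.diabetes_followup is not None:
            raise CohortValidationError(
                f"record {self.id}: censored record carries diabetes_followup"
            )

    @classmethod
    def from_series(cls, row: pd.Series) -> "ParticipantRecord":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            v = row[f]
            if pd.isna(v):
                v = None
            kwargs[f] = v
        rec = cls(**kwargs)
        rec.validate()
        return rec


@dataclass
class EligibilityReport:
    """Counts from baseline eligibility screening.

    A record failing both criteria is counted once, under hypertension.
    """

    n_input: int
    n_excluded_hypertension: int
    n_excluded_diabetes: int
    n_eligible: int
    excluded_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        total = self.n_eligible + self.n_excluded_hypertension + self.n_excluded_diabetes
        if total != self.n_input:
            raise CohortValidationError(
                f"eligibility counts do not reconcile: {total} != {self.n_input}"
            )


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def average_bp(sbp1, sbp2, dbp1, dbp2, ids: Sequence | None = None):
    """Combine the two same-day BP readings by arithmetic mean.

    Parameters are scalars or equal-length arrays (mmHg). Returns the pair
    ``(sbp, dbp)`` of averaged readings. Raises :class:`CohortValidationError`
    naming the offending record for non-positive or inverted readings.
    """
    scalar = np.isscalar(sbp1)
    s1, s2, d1, d2 = map(_asarray, (sbp1, sbp2, dbp1, dbp2))
    s1, s2, d1, d2 = np.atleast_1d(s1, s2, d1, d2)
    bad = ~((s1 > 0) & (s2 > 0) & (d1 > 0) & (d2 > 0) & (s1 > d1) & (s2 > d2))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        label = ids[idx] if ids is not None else f"index {idx}"
        raise CohortValidationError(
            f"record {label}: non-positive or inverted BP reading"
        )
    sbp = (s1 + s2) / 2.0
    dbp = (d1 + d2) / 2.0
    if scalar:
        return float(sbp[0]), float(dbp[0])
    return sbp, dbp


def classify_bp(sbp, dbp):
    """Classify averaged BP under JNC-7 and JNC-6 simultaneously.

    The category is the highest band triggered by either component; band
    lower bounds are inclusive (SBP exactly 120 is pre-hypertension, exactly
    130 is high-normal, exactly 140 is hypertension).

    Returns a :class:`BPCategory` for scalar input, otherwise a pair of
    string arrays ``(jnc7, jnc6)``.
    """
    scalar = np.isscalar(sbp)
    s = np.atleast_1d(_asarray(sbp))
    d = np.atleast_1d(_asarray(dbp))
    hyper = (s >= 140) | (d >= 90)
    high_normal = ~hyper & ((s >= 130) | (d >= 85))
    normal6 = ~hyper & ~high_normal & ((s >= 120) | (d >= 80))

    jnc6 = np.where(
        hyper, "hypertension", np.where(high_normal, "high_normal", np.where(normal6, "normal", "optimal"))
    )
    jnc7 = np.where(
        hyper, "hypertension", np.where(high_normal | normal6, "prehypertension", "normal")
    )
    if scalar:
        return BPCategory(jnc7=str(jnc7[0]), jnc6=str(jnc6[0]))
    return jnc7.astype(object), jnc6.astype(object)


def diabetes_status(fbg, hba1c, glucose_meds, ids: Sequence | None = None):
    """Diabetes indicator from fasting glucose, HbA1c and medication use.

    True iff fbg >= 126 mg/dL, HbA1c >= 6.5%, or glucose-lowering medication.
    Missing labs are treated as non-qualifying, but a record with all three
    inputs missing raises :class:`IndeterminateStatusError`.
    """
    scalar = np.isscalar(fbg) or fbg is None
    f = np.atleast_1d(np.asarray(fbg, dtype=float))
    h = np.atleast_1d(np.asarray(hba1c, dtype=float))
    m = pd.array(np.atleast_1d(glucose_meds), dtype="boolean")

    all_missing = np.isnan(f) & np.isnan(h) & m.isna()
    if all_missing.any():
        idx = int(np.flatnonzero(all_missing)[0])
        label = ids[idx] if ids is not None else f"index {idx}"
        raise IndeterminateStatusError(
            f"record {label}: fbg, hba1c and glucose_meds all missing"
        )
    meds = m.fillna(False).to_numpy(dtype=bool)
    with np.errstate(invalid="ignore"):
        status = (f >= 126) | (h >= 6.5) | meds
    status = np.where(np.isnan(f), (np.nan_to_num(h) >= 6.5) | meds, status)
    if scalar:
        return bool(status[0])
    return status.astype(bool)


def apply_eligibility(cohort: pd.DataFrame):
    """Drop participants hypertensive or diabetic at baseline.

    Hypertension means averaged BP >= 140/90 in either component *or* the
    ``bp_meds_or_dx`` flag (a prior diagnosis or antihypertensive treatment).
    A record failing both criteria is counted once, under hypertension.

    Returns ``(eligible_cohort, EligibilityReport)``.
    """
    n_input = len(cohort)
    if n_input == 0:
        return cohort.copy(), EligibilityReport(0, 0, 0, 0, [])

    ids = cohort["id"].tolist()
    sbp, dbp = average_bp(
        cohort["sbp1"], cohort["sbp2"], cohort["dbp1"], cohort["dbp2"], ids=ids
    )
    _, jnc6 = classify_bp(sbp, dbp)
    meds = cohort["bp_meds_or_dx"].fillna(False).to_numpy(dtype=bool)
    hyper = (jnc6 == "hypertension") | meds
    diab = diabetes_status(
        cohort["fbg"], cohort["hba1c"], cohort["glucose_meds"], ids=ids
    )
    excl_htn = hyper
    excl_dm = ~hyper & diab
    keep = ~excl_htn & ~excl_dm
    report = EligibilityReport(
        n_input=n_input,
        n_excluded_hypertension=int(excl_htn.sum()),
        n_excluded_diabetes=int(excl_dm.sum()),
        n_eligible=int(keep.sum()),
        excluded_ids=cohort.loc[~keep, "id"].tolist(),
    )
    return cohort.loc[keep].reset_index(drop=True), report
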