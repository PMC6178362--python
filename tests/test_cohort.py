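import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iptwrisk.cohort import (
    CohortValidationError,
    IndeterminateStatusError,
    ParticipantRecord,
    apply_eligibility,
    average_bp,
    classify_bp,
    diabetes_status,
)


class TestAverageBP:
    def test_arithmetic_mean_of_the_two_readings(self):
        assert average_bp(120, 118, 80, 78) == (119.0, 79.0)
        assert average_bp(110, 110, 70, 70) == (110.0, 70.0)

    def test_invalid_reading_raises_naming_the_record(self):
        with pytest.raises(CohortValidationError, match="R07"):
            average_bp([115], [0], [70], [70], ids=["R07"])
        with pytest.raises(CohortValidationError):
            average_bp(70, 70, 80, 80)  # inverted


class TestClassifyBP:
    @pytest.mark.parametrize(
        "sbp, dbp, jnc7, jnc6",
        [
            (110, 70, "normal", "optimal"),
            (118, 85, "prehypertension", "high_normal"),  # DBP drives the band
            (125, 70, "prehypertension", "normal"),
            (145, 70, "hypertension", "hypertension"),
            # inclusive lower bounds of each band
            (120, 70, "prehypertension", "normal"),
            (130, 70, "prehypertension", "high_normal"),
            (140, 70, "hypertension", "hypertension"),
            (110, 80, "prehypertension", "normal"),
            (110, 85, "prehypertension", "high_normal"),
            (110, 90, "hypertension", "hypertension"),
            (119.9, 79.9, "normal", "optimal"),
        ],
    )
    def test_band_assignment(self, sbp, dbp, jnc7, jnc6):
        cat = classify_bp(sbp, dbp)
        assert (cat.jnc7, cat.jnc6) == (jnc7, jnc6)

    def test_acc_alias(self):
        assert classify_bp(125, 70).acc == "elevated"
        assert classify_bp(135, 70).acc == "stage1_hypertension"

    @given(st.integers(80, 200), st.integers(40, 130))
    def test_schemes_partition_consistently(self, sbp, dbp):
        """Cross-scheme invariants hold on the whole measurement grid."""
        cat = classify_bp(sbp, dbp)
        assert cat.jnc7 in ("normal", "prehypertension", "hypertension")
        assert cat.jnc6 in ("optimal", "normal", "high_normal", "hypertension")
        assert (cat.jnc7 == "normal") == (cat.jnc6 == "optimal")
        assert (cat.jnc7 == "prehypertension") == (
            cat.jnc6 in ("normal", "high_normal")
        )
        assert (cat.jnc7 == "hypertension") == (cat.jnc6 == "hypertension")

    @given(st.integers(80, 199), st.integers(40, 130))
    def test_monotone_in_systolic(self, sbp, dbp):
        """Raising SBP never moves the category to a lower band."""
        order7 = ("normal", "prehypertension", "hypertension")
        a = classify_bp(sbp, dbp)
        b = classify_bp(sbp + 1, dbp)
        assert order7.index(b.jnc7) >= order7.index(a.jnc7)


class TestDiabetesStatus:
    @pytest.mark.parametrize(
        "fbg, hba1c, meds, expected",
        [
            (130, 5.2, False, True),
            (100, 6.5, False, True),
            (100, 5.0, True, True),
            (100, 5.0, False, False),
            (126, 5.0, False, True),  # threshold inclusive
            (None, 6.4, False, False),
            (None, None, True, True),
        ],
    )
    def test_definition(self, fbg, hba1c, meds, expected):
        assert diabetes_status(fbg, hba1c, meds) is expected

    def test_all_inputs_missing_is_indeterminate(self):
        with pytest.raises(IndeterminateStatusError):
            diabetes_status(None, None, None)


class TestEligibility:
    def test_exclusions_and_reconciliation(self, record_factory, cohort_factory):
        rows = [
            record_factory(0, sbp1=150, sbp2=150),  # measured hypertension
            record_factory(1, bp_meds_or_dx=True),  # treated/diagnosed
            record_factory(2, fbg=126.0),  # baseline diabetes
            record_factory(3, sbp1=150, sbp2=150, fbg=200.0),  # both -> counted once
            record_factory(4, sbp1=118, sbp2=118, dbp1=76, dbp2=76, fbg=90.0),
        ]
        cohort = cohort_factory(rows)
        eligible, report = apply_eligibility(cohort)
        assert report.n_input == 5
        assert report.n_excluded_hypertension == 3
        assert report.n_excluded_diabetes == 1
        assert report.n_eligible == 1
        assert eligible["id"].tolist() == ["P0004"]
        assert set(report.excluded_ids) == {"P0000", "P0001", "P0002", "P0003"}

    def test_empty_input_is_not_an_error(self, cohort_factory, record_factory):
        empty = cohort_factory([record_factory(0)]).iloc[0:0]
        out, report = apply_eligibility(empty)
        assert len(out) == 0
        assert (report.n_input, report.n_eligible) == (0, 0)


class TestParticipantRecord:
    def test_valid_record_roundtrip(self, record_factory):
        rec = ParticipantRecord.from_series(pd.Series(record_factory(1)))
        assert rec.id == "P0001"

    @pytest.mark.parametrize(
        "overrides",
        [
            {"sex": "unknown"},
            {"bmi": -1.0},
            {"sbp1": 60.0},  # below dbp1
            {"diabetes_followup": None},  # followed up but missing outcome
            {"followup_observed": False},  # censored but outcome present
        ],
    )
    def test_invariant_violations_raise(self, record_factory, overrides):
        with pytest.raises(CohortValidationError):
            ParticipantRecord.from_series(pd.Series(record_factory(1, **overrides)))
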