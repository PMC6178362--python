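import numpy as np
import pandas as pd
import pytest

from iptwrisk.cohort import apply_eligibility
from iptwrisk.pipeline import classify_cohort
from iptwrisk.simulate import (
    SimulationConfig,
    SimulationError,
    calibrate,
    generate_cohort,
    true_marginal_effects,
)


class TestGenerateCohort:
    def test_same_seed_reproduces_cohort(self):
        cfg = SimulationConfig(seed=77, n=500)
        df1, t1 = generate_cohort(cfg)
        df2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(df1, df2)
        assert t1.risks == t2.risks

    def test_exposure_prevalence_matches_cohort_target(self):
        """n=2,941 with marginal prevalence 0.536 gives ~1,577 exposed."""
        cfg = SimulationConfig(seed=2, n=2941)
        df, _ = generate_cohort(cfg)
        n_exposed = (classify_cohort(df)["jnc7"] == "prehypertension").sum()
        sd = np.sqrt(2941 * 0.536 * 0.464)
        assert abs(n_exposed - 1577) < 3 * sd

    def test_table_marginals(self):
        cfg = SimulationConfig(seed=3, n=20_000)
        df, _ = generate_cohort(cfg)
        assert df["age"].mean() == pytest.approx(49.6, abs=0.3)
        assert df["bmi"].mean() == pytest.approx(27.4, abs=0.3)
        assert (df["sex"] == "male").mean() == pytest.approx(0.428, abs=0.02)
        assert (~df["followup_observed"]).mean() == pytest.approx(0.10, abs=0.015)
        assert df["age"].between(40, 64).all()

    def test_bp_consistent_with_assigned_category(self):
        df, _ = generate_cohort(SimulationConfig(seed=4, n=2000))
        cls = classify_cohort(df)
        assert set(cls["jnc7"]) <= {"normal", "prehypertension"}
        # baseline eligibility holds by construction
        eligible, report = apply_eligibility(df)
        assert report.n_eligible == len(df)

    def test_censored_records_have_missing_outcome(self):
        df, _ = generate_cohort(SimulationConfig(seed=5, n=2000))
        censored = ~df["followup_observed"]
        assert censored.any()
        assert df.loc[censored, "diabetes_followup"].isna().all()
        assert df.loc[~censored, "diabetes_followup"].notna().all()

    def test_three_level_mode(self):
        df, truth = generate_cohort(
            SimulationConfig(seed=6, n=3000, exposure_mode="three-level")
        )
        cls = classify_cohort(df)
        assert set(cls["jnc6"]) == {"optimal", "normal", "high_normal"}
        assert set(truth.risk_ratio) == {"normal", "high_normal"}
        assert truth.reference == "optimal"

    def test_risk_above_one_is_rejected(self):
        cfg = SimulationConfig(seed=7, n=500, baseline_risk=0.6)
        with pytest.raises(SimulationError, match="risk"):
            generate_cohort(cfg)

    def test_crude_rr_unbiased_without_confounding(self):
        """With all exposure-model coefficients zero the crude RR converges
        to the generating RR (no-confounding limit)."""
        cfg = SimulationConfig(
            seed=8,
            n=50_000,
            exposure_coefs={},
            cluster_sd=0.0,
            censoring_coefs={},
            censoring_rate=1e-6,
            log_rr=np.log(2.0),
        )
        df, _ = generate_cohort(cfg)
        cls = classify_cohort(df)
        exposed = (cls["jnc7"] == "prehypertension").to_numpy()
        y = df["diabetes_followup"].to_numpy(dtype=float)
        a, n1 = y[exposed].sum(), exposed.sum()
        c, n0 = y[~exposed].sum(), (~exposed).sum()
        log_rr = np.log((a / n1) / (c / n0))
        mc_se = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
        assert abs(log_rr - np.log(2.0)) < 3 * mc_se


class TestTruth:
    def test_null_exposure_effect(self):
        cfg = SimulationConfig(seed=9, log_rr=0.0)
        truth = true_marginal_effects(cfg, n_mc=100_000)
        assert truth.risk_ratio["prehypertension"] == pytest.approx(1.0, abs=1e-12)
        assert truth.ate["prehypertension"] == pytest.approx(0.0, abs=1e-12)

    def test_marginal_rr_equals_exposure_coefficient(self):
        """Log link + covariate-constant effect: the marginal RR is exactly
        exp(coefficient); MC recovers it within reported error."""
        cfg = SimulationConfig(seed=10)
        truth = true_marginal_effects(cfg, n_mc=200_000)
        rr = truth.risk_ratio["prehypertension"]
        assert rr == pytest.approx(1.30, abs=1e-9)
        assert truth.mc_se["prehypertension"] > 0

    def test_risk_scale_doubles_with_baseline_leaving_rr(self):
        cfg1 = SimulationConfig(seed=11, baseline_risk=0.05)
        cfg2 = SimulationConfig(seed=11, baseline_risk=0.10)
        t1 = true_marginal_effects(cfg1, n_mc=50_000, seed=99)
        t2 = true_marginal_effects(cfg2, n_mc=50_000, seed=99)
        for lv in ("normal", "prehypertension"):
            assert t2.risks[lv] == pytest.approx(2 * t1.risks[lv], rel=1e-9)
        assert t2.risk_ratio["prehypertension"] == pytest.approx(
            t1.risk_ratio["prehypertension"], rel=1e-12
        )

    def test_truth_independent_of_exposure_assignment(self):
        """Counterfactual risks come from the outcome law, not the fitted or
        generating exposure model."""
        base = SimulationConfig(seed=12, n=5000)
        flat = SimulationConfig(seed=12, n=5000, exposure_coefs={})
        _, t1 = generate_cohort(base)
        _, t2 = generate_cohort(flat)
        for lv in t1.risks:
            assert t1.risks[lv] == pytest.approx(t2.risks[lv], rel=1e-12)


class TestCalibration:
    def test_intercepts_hit_targets(self):
        cfg = SimulationConfig(seed=1)
        cal = calibrate(cfg)
        df, _ = generate_cohort(SimulationConfig(seed=13, n=50_000), intercepts=cal)
        cls = classify_cohort(df)
        assert (cls["jnc7"] == "prehypertension").mean() == pytest.approx(
            0.536, abs=0.01
        )
        assert (~df["followup_observed"]).mean() == pytest.approx(0.10, abs=0.008)

    def test_seed_is_mandatory(self):
        with pytest.raises(SimulationError):
            SimulationConfig(seed=None)
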