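import numpy as np
import pandas as pd
import pytest

from iptwrisk.effects import (
    EffectsError,
    cluster_bootstrap_ci,
    crude_risk_ratio,
    estimate_effects,
    fit_weighted_log_binomial,
    risk_difference_ate,
    weighted_group_risks,
)

from conftest import gformula_risks


def msm_design(level, exposed="1"):
    return pd.DataFrame(
        {"intercept": np.ones(len(level)), f"exposure[{exposed}]": (np.asarray(level) == exposed).astype(float)}
    )


class TestWeightedGroupRisks:
    def test_uniform_weights_are_proportions(self):
        y = [1, 0, 1, 0, 1]
        lvl = ["a", "a", "b", "b", "b"]
        risks = weighted_group_risks(y, lvl, np.ones(5))
        assert risks == {"a": 0.5, "b": pytest.approx(2 / 3)}

    def test_hajek_hand_example(self):
        risks = weighted_group_risks(
            [1, 0, 1, 0], ["1", "1", "0", "0"], [2.0, 1.0, 1.0, 3.0]
        )
        assert risks["1"] == pytest.approx(2 / 3)
        assert risks["0"] == pytest.approx(1 / 4)

    def test_empty_level_raises(self):
        with pytest.raises(EffectsError, match="b"):
            weighted_group_risks([1, 0], ["a", "b"], [1.0, 0.0])


class TestGFormulaOracle:
    def test_iptw_hajek_equals_standardization(self, toy_population):
        """On a fully enumerated discrete population with exact propensities
        the Hajek IPTW risks equal the g-formula standardized risks."""
        pop = toy_population
        w = pop["prob"] * pop["ipw"]
        risks = weighted_group_risks(pop["Y"], pop["A"].astype(str), w)
        oracle = gformula_risks()
        assert risks["1"] == pytest.approx(oracle[1], abs=1e-12)
        assert risks["0"] == pytest.approx(oracle[0], abs=1e-12)
        assert oracle == {1: pytest.approx(0.20), 0: pytest.approx(0.10)}

    def test_random_discrete_populations(self):
        """Brute-force oracle equivalence on randomly drawn discrete laws."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            pL = rng.dirichlet(np.ones(3))
            pA = rng.uniform(0.1, 0.9, size=3)
            risk = rng.uniform(0.05, 0.6, size=(2, 3))
            rows = []
            p_a1 = float(pL @ pA)
            for l in range(3):
                for a in (0, 1):
                    pa = pA[l] if a else 1 - pA[l]
                    for y in (0, 1):
                        py = risk[a, l] if y else 1 - risk[a, l]
                        rows.append(
                            (str(a), y, pL[l] * pa * py, (p_a1 if a else 1 - p_a1) / pa)
                        )
            lvl, y, prob, ipw = map(np.asarray, zip(*rows))
            risks = weighted_group_risks(y, lvl, prob.astype(float) * ipw.astype(float))
            for a in (0, 1):
                standardized = float(pL @ risk[a])
                assert risks[str(a)] == pytest.approx(standardized, abs=1e-12)

    def test_ate_matches_oracle(self, toy_population):
        pop = toy_population
        w = (pop["prob"] * pop["ipw"]).to_numpy()
        ate, se, ci, risks = risk_difference_ate(
            pop["Y"], pop["A"].astype(str), w, np.arange(len(pop)), ("1", "0")
        )
        assert ate == pytest.approx(0.10, abs=1e-12)

    def test_saturated_glm_equals_hajek_ratio(self, toy_population):
        """exp(exposure coefficient) of the weighted log-binomial equals the
        ratio of the two Hajek risks for the saturated model."""
        pop = toy_population
        w = (pop["prob"] * pop["ipw"]).to_numpy() * 1000
        lvl = pop["A"].astype(str).to_numpy()
        glm = fit_weighted_log_binomial(
            msm_design(lvl), pop["Y"].to_numpy(), w, np.arange(len(pop))
        )
        risks = weighted_group_risks(pop["Y"], lvl, w)
        assert glm["rr"]["exposure[1]"] == pytest.approx(
            risks["1"] / risks["0"], abs=1e-10
        )


class TestRiskDifference:
    def test_identical_risks_give_zero(self):
        y = np.array([1, 0, 1, 0])
        lvl = np.array(["1", "1", "0", "0"])
        ate, *_ = risk_difference_ate(y, lvl, np.ones(4), ["c1", "c2", "c1", "c2"], ("1", "0"))
        assert ate == 0.0

    def test_published_weighted_risks_reproduce_reported_ate(self):
        from iptwrisk.effects import risk_difference_from_risks

        assert risk_difference_from_risks(0.121, 0.107) == pytest.approx(0.014)

    def test_single_cluster_raises_unless_allowed(self):
        y = np.array([1, 0, 1, 0])
        lvl = np.array(["1", "1", "0", "0"])
        with pytest.raises(EffectsError):
            risk_difference_ate(y, lvl, np.ones(4), np.zeros(4), ("1", "0"))
        ate, se, ci, _ = risk_difference_ate(
            y, lvl, np.ones(4), np.zeros(4), ("1", "0"), allow_unclustered=True
        )
        assert se > 0


class TestLogBinomial:
    def test_two_by_two_closed_form(self):
        y = np.concatenate([np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)])
        lvl = np.array(["1"] * 100 + ["0"] * 100)
        glm = fit_weighted_log_binomial(
            msm_design(lvl), y, np.ones(200), np.arange(200)
        )
        assert glm["params"]["intercept"] == pytest.approx(np.log(0.10), abs=1e-8)
        assert glm["params"]["exposure[1]"] == pytest.approx(np.log(2.0), abs=1e-8)
        assert glm["method"] == "log-binomial"

    def test_zero_coefficient_for_equal_risks(self):
        y = np.tile([1, 0, 0, 0], 20)
        lvl = np.array((["1"] * 4 + ["0"] * 4) * 10)
        glm = fit_weighted_log_binomial(msm_design(lvl), y, np.ones(80), np.arange(80))
        assert glm["params"]["exposure[1]"] == pytest.approx(0.0, abs=1e-8)

    def test_record_level_clusters_equal_hc0(self):
        """With every record its own cluster the cluster sandwich is the
        HC0 heteroskedasticity-robust variance."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        lvl = rng.choice(["0", "1"], 300)
        p = np.where(lvl == "1", 0.2, 0.1)
        y = (rng.random(300) < p).astype(float)
        X = msm_design(lvl)
        glm = fit_weighted_log_binomial(X, y, np.ones(300), np.arange(300))
        ref = sm.GLM(
            y,
            np.asarray(X),
            family=sm.families.Binomial(link=sm.families.links.Log()),
        ).fit(start_params=glm["params"].to_numpy(), cov_type="HC0")
        np.testing.assert_allclose(glm["bse"].to_numpy(), ref.bse, rtol=1e-6)


class TestCrudeRiskRatio:
    def test_wald_interval_closed_form(self):
        rr, se, ci = crude_risk_ratio(20, 100, 10, 100)
        assert rr == pytest.approx(2.0)
        assert se == pytest.approx(np.sqrt(0.13))
        # exp(log 2 -/+ 1.96 * sqrt(0.13)) = (0.9866, 4.0546)
        assert ci[0] == pytest.approx(0.9866, abs=1e-3)
        assert ci[1] == pytest.approx(4.0546, abs=1e-3)

    def test_equal_risks_give_unity(self):
        rr, *_ = crude_risk_ratio(5, 50, 10, 100)
        assert rr == pytest.approx(1.0)

    def test_zero_cell_raises(self):
        with pytest.raises(EffectsError, match="continuity"):
            crude_risk_ratio(0, 100, 10, 100)


class TestEstimateEffects:
    def test_contrast_consistency(self):
        rng = np.random.default_rng(8)
        n = 400
        lvl = rng.choice(["normal", "prehypertension"], n)
        y = (rng.random(n) < np.where(lvl == "prehypertension", 0.15, 0.1)).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        clusters = rng.integers(0, 20, n)
        est = estimate_effects(
            y, lvl, w, clusters, reference="normal", exposed_levels=["prehypertension"]
        )
        c = est.contrasts[0]
        assert c.risk_difference == pytest.approx(
            c.risk_exposed - c.risk_reference, abs=1e-12
        )
        # saturated MSM: GLM RR equals the ratio of Hajek risks
        assert c.risk_ratio == pytest.approx(
            c.risk_exposed / c.risk_reference, abs=1e-10
        )
        assert c.rd_ci[0] <= c.risk_difference <= c.rd_ci[1]
        assert c.rr_ci[0] <= c.risk_ratio <= c.rr_ci[1]
        assert 0 < est.effective_n["normal"] <= est.n["normal"]

    def test_cluster_bootstrap_interval(self):
        rng = np.random.default_rng(9)
        n = 300
        lvl = rng.choice(["0", "1"], n)
        y = (rng.random(n) < np.where(lvl == "1", 0.3, 0.15)).astype(float)
        clusters = rng.integers(0, 30, n)
        lo, hi = cluster_bootstrap_ci(
            y, lvl, np.ones(n), clusters, ("1", "0"), reps=199, seed=4
        )
        assert lo < hi
        with pytest.raises(EffectsError):
            cluster_bootstrap_ci(y, lvl, np.ones(n), clusters, ("1", "0"), seed=None)
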