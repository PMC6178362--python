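import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_record(i=0, **overrides):
    """One valid cohort row as a dict (normotensive, non-diabetic)."""
    row = {
        "id": f"P{i:04d}",
        "cluster_id": f"C{i % 3:02d}",
        "age": 50.0,
        "sex": "female",
        "marital_status": "married",
        "education_years": 8.0,
        "economic_status": "high",
        "smoking": False,
        "bmi": 27.0,
        "sbp1": 112.0,
        "sbp2": 110.0,
        "dbp1": 72.0,
        "dbp2": 70.0,
        "fbg": 95.0,
        "hba1c": 5.2,
        "glucose_meds": False,
        "bp_meds_or_dx": False,
        "followup_observed": True,
        "diabetes_followup": False,
    }
    row.update(overrides)
    return row


def make_cohort(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def cohort_factory():
    return make_cohort


# -- enumerated discrete population with exact propensities -------------------
#
# L ~ Bernoulli(0.5); Pr(A=1|L) = 0.2 / 0.8; risk(Y=1|A,L):
#   (A=0,L=0)=0.05, (A=0,L=1)=0.15, (A=1,L=0)=0.10, (A=1,L=1)=0.30
# Standardized (g-formula) risks: risk(A=1)=0.20, risk(A=0)=0.10.

TOY_P_L = {0: 0.5, 1: 0.5}
TOY_P_A_GIVEN_L = {0: 0.2, 1: 0.8}
TOY_RISK = {(0, 0): 0.05, (0, 1): 0.15, (1, 0): 0.10, (1, 1): 0.30}


def enumerate_toy_population():
    """All (L, A, Y) cells with joint probability and exact stabilized IPW."""
    p_a1 = sum(TOY_P_L[l] * TOY_P_A_GIVEN_L[l] for l in TOY_P_L)
    rows = []
    for l in (0, 1):
        for a in (0, 1):
            p_a = TOY_P_A_GIVEN_L[l] if a == 1 else 1 - TOY_P_A_GIVEN_L[l]
            for y in (0, 1):
                p_y = TOY_RISK[(a, l)] if y == 1 else 1 - TOY_RISK[(a, l)]
                rows.append(
                    {
                        "L": l,
                        "A": a,
                        "Y": y,
                        "prob": TOY_P_L[l] * p_a * p_y,
                        "ipw": (p_a1 if a == 1 else 1 - p_a1) / p_a,
                    }
                )
    return pd.DataFrame(rows)


def gformula_risks():
    """Brute-force standardization oracle over the enumerated joint."""
    return {
        a: sum(TOY_P_L[l] * TOY_RISK[(a, l)] for l in TOY_P_L) for a in (0, 1)
    }


@pytest.fixture
def toy_population():
    return enumerate_toy_population()


@pytest.fixture(scope="session")
def sim_cohort():
    """Seed-fixed default confounded cohort (n=3000) with its causal truth."""
    from iptwrisk.simulate import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig(seed=123, n=3000))


@pytest.fixture(scope="session")
def sim_analysis(sim_cohort):
    """Full weighted analysis of the seed-fixed cohort."""
    from iptwrisk.pipeline import analyze

    cohort, _ = sim_cohort
    return analyze(cohort)
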