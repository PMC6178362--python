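"""Published baseline characteristics and headline estimates of the Shahroud
40-64-year cohort study of blood-pressure category and diabetes incidence.

These constants serve two purposes: they parameterize the synthetic-data
generator (the simulated cohort reproduces the published marginals), and they
are the fixture for internal-consistency checks (the published weighted risks,
risk ratio and ATE must reconcile arithmetically). Counts are stored rather
than printed percentages, since percentages can be re-derived.
"""

from __future__ import annotations

__all__ = [
    "BASELINE",
    "WEIGHTED_RISKS",
    "REPORTED",
]

#: Baseline cohort characteristics by JNC-7 exposure group (counts and
#: mean/SD pairs). "exposed" = pre-hypertension, "unexposed" = normal BP.
BASELINE = {
    "n_total": 2941,
    "n_exposed": 1577,
    "n_unexposed": 1364,
    "n_censored": 295,
    "male": {"exposed": 751, "unexposed": 507, "total": 1258},
    "female": {"exposed": 826, "unexposed": 857, "total": 1683},
    "age_mean_sd": {"exposed": (50.1, 6.1), "unexposed": (49.0, 5.7), "total": (49.6, 5.9)},
    "bmi_mean_sd": {"exposed": (28.1, 4.7), "unexposed": (26.7, 4.7), "total": (27.4, 4.7)},
    "education_mean_sd": {"exposed": (7.6, 4.6), "unexposed": (7.5, 4.5), "total": (7.6, 4.6)},
    "smoking": {"exposed": 197, "unexposed": 205, "total": 402},
    "economic_status": {
        "high": {"exposed": 748, "unexposed": 643, "total": 1391},
        "medium": {"exposed": 437, "unexposed": 378, "total": 815},
        "low": {"exposed": 389, "unexposed": 342, "total": 731},
    },
    "incident_diabetes": {"exposed": 179, "unexposed": 119},
}

#: Published IPTW-weighted 5-year diabetes risks (proportions) per exposure
#: level under each classification scheme.
WEIGHTED_RISKS = {
    "jnc7": {"normal": 0.107, "prehypertension": 0.121},
    "jnc6": {"optimal": 0.097, "normal": 0.107, "high_normal": 0.153},
}

#: Published effect estimates. The high-normal RR appears as 1.31 in the
#: abstract and 1.32 in the results table; both are retained with provenance.
REPORTED = {
    "jnc7_rr": 1.13,
    "jnc7_rr_ci": (0.90, 1.41),
    "jnc7_ate_percent": 1.4,
    "jnc7_ate_ci_percent": (-1.1, 3.4),
    "jnc6_normal_rr": 0.96,
    "jnc6_normal_rr_ci": (0.73, 1.25),
    "jnc6_high_normal_rr": {"abstract": 1.31, "results_table": 1.32},
    "jnc6_high_normal_rr_ci": (1.01, 1.72),
    "crude_risk_exposed": 0.127,
    "crude_risk_unexposed": 0.097,
}
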