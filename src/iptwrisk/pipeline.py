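"""End-to-end analysis: eligibility -> BP classification -> exposure and
censoring models -> stabilized weights -> counterfactual effects ->
diagnostics.

The JNC-7 analysis contrasts pre-hypertension against normal BP; the JNC-6
analysis contrasts normal and high-normal BP against optimal BP (two
contrasts, optimal as reference). Confounders enter only through the weights;
the outcome model contains exposure indicators alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort import EligibilityReport, apply_eligibility, average_bp, classify_bp
from .design import (
    CovariateSpec,
    build_design,
    default_censoring_spec,
    default_exposure_spec,
)
from .diagnostics import BalanceTable, balance_table, weight_summary
from .effects import CausalEstimate, estimate_effects
from .io import PipelineConfig, read_cohort_csv
from .propensity import (
    PropensityFit,
    fit_binary_logistic,
    fit_multinomial,
    predict_probabilities,
)
from .weights import WeightSet, combine_and_truncate, stabilized_censoring_weights, stabilized_exposure_weights

__all__ = ["SCHEMES", "AnalysisResult", "classify_cohort", "analyze", "run_pipeline"]

logger = logging.getLogger(__name__)

#: exposure levels per scheme: (reference, non-reference levels in order)
SCHEMES = {
    "jnc7": ("normal", ("prehypertension",)),
    "jnc6": ("optimal", ("normal", "high_normal")),
}

#: cohort fields any default model spec may touch
_MODEL_FIELDS = (
    "age",
    "sex",
    "marital_status",
    "education_years",
    "economic_status",
    "smoking",
    "bmi",
)


@dataclass
class AnalysisResult:
    """Everything the pipeline produces for one cohort and scheme."""

    scheme: str
    eligibility: EligibilityReport
    counts: dict
    exposure_fit: PropensityFit
    censoring_fit: PropensityFit | None
    weights: WeightSet
    estimate: CausalEstimate
    balance: BalanceTable | None
    weight_stats: dict
    marginals: dict
    ids: pd.Series
    level: np.ndarray
    observed: np.ndarray

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids.to_numpy(),
                "sw_treatment": self.weights.sw_treatment,
                "sw_censoring": self.weights.sw_censoring,
                "combined": self.weights.combined,
            }
        )


def classify_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append averaged BP and both scheme classifications as columns."""
    out = cohort.copy()
    sbp, dbp = average_bp(
        cohort["sbp1"], cohort["sbp2"], cohort["dbp1"], cohort["dbp2"],
        ids=cohort["id"].tolist(),
    )
    jnc7, jnc6 = classify_bp(sbp, dbp)
    out["sbp_avg"] = sbp
    out["dbp_avg"] = dbp
    out["jnc7"] = jnc7
    out["jnc6"] = jnc6
    return out


def _complete_cases(cohort: pd.DataFrame) -> pd.DataFrame:
    fields = [*_MODEL_FIELDS, "cluster_id", "sbp1", "sbp2", "dbp1", "dbp2", "followup_observed"]
    keep = cohort[fields].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("complete-case filter on model covariates dropped %d records", dropped)
    return cohort.loc[keep].reset_index(drop=True)


def analyze(
    cohort: pd.DataFrame,
    scheme: str = "jnc7",
    interaction: bool = True,
    truncation: tuple[float, float] | None = None,
    clip: float = 1e-6,
    ci_method: str = "sandwich",
    bootstrap_reps: int = 999,
    seed: int | None = None,
    censor_numerator: str = "marginal",
    exposure_spec: CovariateSpec | None = None,
    censoring_spec: CovariateSpec | None = None,
    apply_eligibility_filter: bool = True,
    compute_balance: bool = True,
) -> AnalysisResult:
    """Run the weighted analysis on a validated cohort DataFrame.

    Stages: eligibility screen, complete-case filter on model covariates,
    BP classification, exposure propensity model (binary logistic for the
    JNC-7 scheme, multinomial logit for JNC-6), censoring model (logistic for
    remaining under observation), stabilized weights, counterfactual risks /
    ATE / RR on the uncensored weighted sample, and balance diagnostics.
    ``censor_numerator="exposure"`` conditions the censoring-weight numerator
    on the observed exposure level instead of the overall marginal.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    reference, exposed_levels = SCHEMES[scheme]

    n_input = len(cohort)
    if apply_eligibility_filter:
        cohort, report = apply_eligibility(cohort)
    else:
        report = EligibilityReport(n_input, 0, 0, n_input, [])
    cohort = _complete_cases(cohort)
    cohort = classify_cohort(cohort)
    level = cohort[scheme].to_numpy(dtype=object)
    logger.info(
        "scheme %s: %s", scheme,
        {lv: int((level == lv).sum()) for lv in dict.fromkeys(level)},
    )

    # exposure propensity model
    exposure_spec = exposure_spec or default_exposure_spec(interaction)
    X_exp, exp_info = build_design(cohort, exposure_spec)
    all_levels = [reference, *exposed_levels]
    if scheme == "jnc7":
        y_exp = (level == exposed_levels[0]).astype(float)
        exp_fit = fit_binary_logistic(X_exp, y_exp)
        p1 = predict_probabilities(exp_fit, X_exp, clip=clip)
        cond = np.where(y_exp == 1, p1, 1 - p1)
    else:
        exp_fit = fit_multinomial(X_exp, level, reference=reference, levels=all_levels)
        probs = predict_probabilities(exp_fit, X_exp, clip=clip)
        idx = np.array([exp_fit.levels.index(lv) for lv in level])
        cond = probs[np.arange(len(level)), idx]
    marginal = {lv: float((level == lv).mean()) for lv in all_levels}
    sw_t = stabilized_exposure_weights(level, marginal, cond)

    # censoring model
    observed = cohort["followup_observed"].to_numpy(dtype=bool)
    n_censored = int((~observed).sum())
    if n_censored == 0:
        cens_fit = None
        sw_c = np.ones(len(cohort))
    else:
        censoring_spec = censoring_spec or default_censoring_spec()
        X_cens, _ = build_design(cohort, censoring_spec)
        cens_fit = fit_binary_logistic(X_cens, observed.astype(float))
        cond_unc = predict_probabilities(cens_fit, X_cens, clip=clip)
        if censor_numerator == "exposure":
            marg_unc = np.empty(len(cohort))
            for lv in all_levels:
                m = level == lv
                marg_unc[m] = observed[m].mean()
            sw_c = marg_unc / cond_unc
        else:
            sw_c = stabilized_censoring_weights(observed, observed.mean(), cond_unc)
    wset = combine_and_truncate(sw_t, sw_c, truncation=truncation)

    # effects on the uncensored weighted sample
    y = cohort["diabetes_followup"].to_numpy()[observed].astype(float)
    estimate = estimate_effects(
        y,
        level[observed],
        wset.combined[observed],
        cohort["cluster_id"].to_numpy()[observed],
        reference=reference,
        exposed_levels=list(exposed_levels),
        ci_method=ci_method,
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )

    balance = None
    if compute_balance:
        balance = balance_table(
            cohort, level, wset.sw_treatment, exposure_spec, reference=reference
        )
    n_clipped = exp_fit.n_clipped + (cens_fit.n_clipped if cens_fit else 0)
    wstats = weight_summary(
        wset.combined[observed], n_clipped=n_clipped, n_truncated=wset.n_truncated
    )
    counts = {
        "n_input": n_input,
        "n_eligible": report.n_eligible,
        "n_modeled": len(cohort),
        "n_censored": n_censored,
        "n_analyzed": int(observed.sum()),
    }
    logger.info("record flow: %s", counts)
    return AnalysisResult(
        scheme=scheme,
        eligibility=report,
        counts=counts,
        exposure_fit=exp_fit,
        censoring_fit=cens_fit,
        weights=wset,
        estimate=estimate,
        balance=balance,
        weight_stats=wstats,
        marginals=marginal,
        ids=cohort["id"],
        level=level,
        observed=observed,
    )


def _report_text(config: PipelineConfig, result: AnalysisResult) -> str:
    lines = [
        f"iptwrisk {_pkg_version} analysis report",
        "",
        "configuration:",
    ]
    for k, v in dataclasses.asdict(config).items():
        lines.append(f"  {k}: {v}")
    lines += ["", "record flow:"]
    for k, v in result.counts.items():
        lines.append(f"  {k}: {v}")
    lines += ["", "weighted counterfactual risks:"]
    for lv, r in result.estimate.risks.items():
        lines.append(
            f"  {lv}: {100 * r:.1f}%  (n={result.estimate.n[lv]}, "
            f"effective n={result.estimate.effective_n[lv]:.0f})"
        )
    lines += ["", "contrasts:"]
    for c in result.estimate.contrasts:
        lines.append(
            f"  {c.exposed} vs {c.reference}: "
            f"RD {100 * c.risk_difference:.1f} pp "
            f"(95% CI {100 * c.rd_ci[0]:.1f} to {100 * c.rd_ci[1]:.1f}); "
            f"RR {c.risk_ratio:.2f} "
            f"(95% CI {c.rr_ci[0]:.2f} to {c.rr_ci[1]:.2f}) [{c.method}]"
        )
    ws = result.weight_stats
    lines += [
        "",
        "combined stabilized weights (analysis records): "
        f"mean {ws['mean']:.3f}, sd {ws['sd']:.3f}, range "
        f"[{ws['min']:.3f}, {ws['max']:.3f}], clipped {ws['n_clipped']}, "
        f"truncated {ws['n_truncated']}",
    ]
    if result.balance is not None:
        worst = result.balance.table["smd_weighted"].abs().max()
        lines.append(f"max weighted |SMD|: {worst:.3f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Read the cohort, run :func:`analyze`, and write the result bundle.

    Writes ``results.csv``, ``weights.csv``, ``balance.csv`` and
    ``report.txt`` into ``config.output_dir``. Given the same config and
    seed the outputs are byte-identical.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cohort = read_cohort_csv(config.input_path)
    result = analyze(
        cohort,
        scheme=config.scheme,
        interaction=config.interaction,
        truncation=config.truncation,
        clip=config.clip,
        ci_method=config.ci_method,
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
        censor_numerator=config.censor_numerator,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.estimate.to_frame().to_csv(out / "results.csv", index=False)
    result.weights_frame().to_csv(out / "weights.csv", index=False)
    if result.balance is not None:
        result.balance.table.to_csv(out / "balance.csv", index=False)
    (out / "report.txt").write_text(_report_text(config, result))
    logger.info("wrote result bundle to %s", out)
    return result
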