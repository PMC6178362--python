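"""Counterfactual risk, risk-difference (ATE) and risk-ratio estimation in the
weighted pseudo-population.

Per-level risks are Hajek (ratio) estimators: sum(w*y)/sum(w) within each
exposure level of the weighted, uncensored sample. The ATE is the difference
of two Hajek means with a cluster-aggregated influence-function variance
(weights treated as fixed, which ignores propensity-estimation uncertainty and
is conservative for the treatment effect). The risk ratio comes from a
weighted log-link binomial GLM containing only the exposure indicators — a
marginal structural model: confounders act through the weights, not the
outcome model — with a cluster-robust sandwich variance; if the log-binomial
IRLS fails, the estimator falls back to a log-link Poisson working model
("modified Poisson") and tags the estimate accordingly. An optional cluster
bootstrap (resampling whole clusters with replacement) is available as an
alternative interval method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "EffectsError",
    "ContrastEstimate",
    "CausalEstimate",
    "weighted_group_risks",
    "risk_difference_ate",
    "fit_weighted_log_binomial",
    "crude_risk_ratio",
    "risk_ratio_from_risks",
    "risk_difference_from_risks",
    "cluster_bootstrap_ci",
    "estimate_effects",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05  # two-sided significance level for all intervals


class EffectsError(ValueError):
    """Invalid input to an effect estimator."""


def _z(alpha: float) -> float:
    return float(scipy.stats.norm.ppf(1 - alpha / 2))


@dataclass
class ContrastEstimate:
    """One exposure contrast: risk difference and risk ratio with intervals."""

    exposed: str
    reference: str
    risk_exposed: float
    risk_reference: float
    risk_difference: float
    rd_se: float
    rd_ci: tuple[float, float]
    risk_ratio: float
    log_rr_se: float
    rr_ci: tuple[float, float]
    method: str


@dataclass
class CausalEstimate:
    """Counterfactual risks per exposure level plus all requested contrasts."""

    risks: dict[str, float]
    n: dict[str, int]
    effective_n: dict[str, float]
    contrasts: list[ContrastEstimate] = field(default_factory=list)
    alpha: float = ALPHA
    method: str = "hajek+log-binomial/sandwich"

    def to_frame(self) -> pd.DataFrame:
        """Flat results table (one row per contrast and measure)."""
        rows = []
        for c in self.contrasts:
            rows.append(
                {
                    "contrast": f"{c.exposed} vs {c.reference}",
                    "measure": "risk_difference",
                    "estimate": c.risk_difference,
                    "se": c.rd_se,
                    "ci_low": c.rd_ci[0],
                    "ci_high": c.rd_ci[1],
                    "method": c.method,
                }
            )
            rows.append(
                {
                    "contrast": f"{c.exposed} vs {c.reference}",
                    "measure": "risk_ratio",
                    "estimate": c.risk_ratio,
                    "se": c.log_rr_se,
                    "ci_low": c.rr_ci[0],
                    "ci_high": c.rr_ci[1],
                    "method": c.method,
                }
            )
        return pd.DataFrame(rows)


def weighted_group_risks(y, level, w) -> dict[str, float]:
    """Hajek risk per exposure level: sum(w*y)/sum(w) within the level.

    Uniform weights reduce to ordinary group proportions. Raises on an empty
    level or a level with non-positive total weight.
    """
    y = np.asarray(y, dtype=float)
    level = np.asarray(level, dtype=object)
    w = np.asarray(w, dtype=float)
    if not (y.shape == level.shape == w.shape):
        raise EffectsError("y, level and w must have equal length")
    risks: dict[str, float] = {}
    for lv in dict.fromkeys(level):
        mask = level == lv
        tot = w[mask].sum()
        if not mask.any() or tot <= 0:
            raise EffectsError(f"exposure level {lv!r} is empty or has no weight")
        risks[lv] = float((w[mask] * y[mask]).sum() / tot)
    return risks


def _hajek_influence(y, mask, w, mu):
    """Per-record influence of the Hajek mean of group ``mask``."""
    W = w[mask].sum()
    psi = np.zeros(len(y))
    psi[mask] = w[mask] * (y[mask] - mu) / W
    return psi


def _cluster_se(psi: np.ndarray, clusters: np.ndarray) -> float:
    codes, _ = pd.factorize(clusters)
    sums = np.bincount(codes, weights=psi)
    return float(np.sqrt((sums**2).sum()))


def risk_difference_ate(
    y,
    level,
    w,
    clusters,
    contrast: tuple[str, str],
    alpha: float = ALPHA,
    allow_unclustered: bool = False,
):
    """ATE for one contrast: difference of the two Hajek risks.

    The standard error aggregates the records' influence contributions within
    sampling clusters (weights treated as fixed). With a single cluster the
    variance is undefined: this raises, unless ``allow_unclustered`` is set,
    in which case each record is treated as its own cluster with a warning.

    Returns ``(ate, se, (ci_low, ci_high), risks)``.
    """
    y = np.asarray(y, dtype=float)
    level = np.asarray(level, dtype=object)
    w = np.asarray(w, dtype=float)
    clusters = np.asarray(clusters)
    exposed, ref = contrast
    risks = weighted_group_risks(y, level, w)
    for lv in contrast:
        if lv not in risks:
            raise EffectsError(f"contrast level {lv!r} not present")
    ate = risks[exposed] - risks[ref]
    psi = _hajek_influence(y, level == exposed, w, risks[exposed]) - _hajek_influence(
        y, level == ref, w, risks[ref]
    )
    if len(np.unique(clusters)) < 2:
        if not allow_unclustered:
            raise EffectsError(
                "variance undefined with a single cluster; pass allow_unclustered=True "
                "to fall back to record-level (unclustered) variance"
            )
        logger.warning("single cluster: falling back to unclustered variance")
        clusters = np.arange(len(y))
    se = _cluster_se(psi, clusters)
    zz = _z(alpha)
    return ate, se, (ate - zz * se, ate + zz * se), risks


def fit_weighted_log_binomial(
    X: pd.DataFrame,
    y,
    w,
    clusters,
    alpha: float = ALPHA,
):
    """Weighted log-link binomial GLM with a cluster-robust sandwich variance.

    ``X`` must contain an intercept plus exposure indicator columns only (the
    marginal structural model); ``w`` are the combined stabilized weights used
    as importance weights. exp(coefficient) is the risk ratio for that
    indicator. On log-binomial IRLS failure (boundary or non-convergence) the
    fit falls back to a log-link Poisson working model with the same sandwich
    variance and tags ``method = "modified-poisson"``.

    Returns a dict with ``params`` (Series), ``bse`` (robust log-scale SEs),
    ``rr`` / ``rr_ci`` (Series/dict per non-intercept column), ``method`` and
    ``converged``.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    codes, uniques = pd.factorize(np.asarray(clusters))
    if len(uniques) < 2:
        raise EffectsError("variance undefined with a single cluster")
    Xa = np.asarray(X, dtype=float)
    cov_kwds = {"groups": codes, "use_correction": False}
    start = np.zeros(Xa.shape[1])
    ybar = float(np.average(y, weights=w))
    start[list(X.columns).index("intercept")] = np.log(max(ybar, 1e-6))

    method = "log-binomial"
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(
                y,
                Xa,
                family=sm.families.Binomial(link=sm.families.links.Log()),
                var_weights=w,
            )
            res = model.fit(
                start_params=start,
                maxiter=100,
                tol=1e-10,
                cov_type="cluster",
                cov_kwds=cov_kwds,
            )
            mu = np.asarray(res.fittedvalues)
            if not getattr(res, "converged", False) or (mu >= 1 - 1e-12).any():
                raise ValueError("log-binomial IRLS failed or hit the risk boundary")
        except Exception as exc:  # documented fallback path
            logger.warning("log-binomial fit failed (%s); using modified Poisson", exc)
            method = "modified-poisson"
            model = sm.GLM(y, Xa, family=sm.families.Poisson(), var_weights=w)
            res = model.fit(
                maxiter=100, tol=1e-10, cov_type="cluster", cov_kwds=cov_kwds
            )

    params = pd.Series(np.asarray(res.params), index=list(X.columns))
    bse = pd.Series(np.asarray(res.bse), index=list(X.columns))
    zz = _z(alpha)
    rr = {}
    rr_ci = {}
    for col in X.columns:
        if col == "intercept":
            continue
        rr[col] = float(np.exp(params[col]))
        rr_ci[col] = (
            float(np.exp(params[col] - zz * bse[col])),
            float(np.exp(params[col] + zz * bse[col])),
        )
    return {
        "params": params,
        "bse": bse,
        "rr": rr,
        "rr_ci": rr_ci,
        "method": method,
        "converged": bool(getattr(res, "converged", True)),
    }


def crude_risk_ratio(a: int, n1: int, c: int, n0: int, alpha: float = ALPHA):
    """Unadjusted risk ratio from a 2x2 table with a log-scale Wald interval.

    ``a``/``n1`` are exposed cases/total, ``c``/``n0`` unexposed. SE of the
    log RR is sqrt(1/a - 1/n1 + 1/c - 1/n0). Zero cases in either arm raise
    (apply an explicit continuity correction upstream if wanted; none is
    applied silently here).
    """
    if min(n1, n0) <= 0 or a > n1 or c > n0 or min(a, c) < 0:
        raise EffectsError("invalid 2x2 table")
    if a == 0 or c == 0:
        raise EffectsError(
            "zero cases in one arm: the Wald log-RR interval is undefined; "
            "consider a continuity correction"
        )
    rr = (a / n1) / (c / n0)
    se = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    zz = _z(alpha)
    lo, hi = np.exp(np.log(rr) - zz * se), np.exp(np.log(rr) + zz * se)
    return float(rr), float(se), (float(lo), float(hi))


def risk_ratio_from_risks(risk_exposed: float, risk_reference: float) -> float:
    """Ratio of two counterfactual risks."""
    if risk_reference <= 0:
        raise EffectsError("reference risk must be positive")
    return risk_exposed / risk_reference


def risk_difference_from_risks(risk_exposed: float, risk_reference: float) -> float:
    """Difference of two counterfactual risks (the ATE)."""
    return risk_exposed - risk_reference


def cluster_bootstrap_ci(
    y,
    level,
    w,
    clusters,
    contrast: tuple[str, str],
    statistic: str = "risk_ratio",
    reps: int = 999,
    seed: int | None = None,
    alpha: float = ALPHA,
):
    """Percentile interval from resampling whole clusters with replacement.

    ``statistic`` is ``"risk_ratio"`` or ``"risk_difference"``. Replicates in
    which a contrast level vanishes are redrawn implicitly by being skipped;
    the interval uses the remaining replicates.
    """
    if seed is None:
        raise EffectsError("cluster bootstrap requires a seed")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    level = np.asarray(level, dtype=object)
    w = np.asarray(w, dtype=float)
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    by_cluster = {c: np.flatnonzero(clusters == c) for c in uniq}
    exposed, ref = contrast
    stats = []
    for _ in range(reps):
        draw = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([by_cluster[c] for c in draw])
        try:
            risks = weighted_group_risks(y[idx], level[idx], w[idx])
            if statistic == "risk_ratio":
                stats.append(risks[exposed] / risks[ref])
            else:
                stats.append(risks[exposed] - risks[ref])
        except (EffectsError, KeyError, ZeroDivisionError):
            continue
    if len(stats) < reps // 2:
        raise EffectsError("too many degenerate bootstrap replicates")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def estimate_effects(
    y,
    level,
    w,
    clusters,
    reference: str,
    exposed_levels: Sequence[str],
    alpha: float = ALPHA,
    ci_method: str = "sandwich",
    bootstrap_reps: int = 999,
    seed: int | None = None,
) -> CausalEstimate:
    """Full effect estimation for one exposure scheme.

    Computes Hajek risks for every level, the ATE per contrast with the
    influence-function cluster variance, and risk ratios from a single
    weighted log-binomial model containing one indicator per non-reference
    level. ``ci_method="cluster-bootstrap"`` replaces both intervals by
    percentile bootstrap intervals over clusters.
    """
    y = np.asarray(y, dtype=float)
    level = np.asarray(level, dtype=object)
    w = np.asarray(w, dtype=float)
    clusters = np.asarray(clusters)
    risks = weighted_group_risks(y, level, w)

    # one MSM with all exposure indicators, reference absorbed in intercept
    Xcols = {"intercept": np.ones(len(y))}
    for lv in exposed_levels:
        Xcols[f"exposure[{lv}]"] = (level == lv).astype(float)
    X = pd.DataFrame(Xcols)
    glm = fit_weighted_log_binomial(X, y, w, clusters, alpha=alpha)

    n = {lv: int((level == lv).sum()) for lv in risks}
    eff_n = {
        lv: float(w[level == lv].sum() ** 2 / (w[level == lv] ** 2).sum())
        for lv in risks
    }
    est = CausalEstimate(risks=risks, n=n, effective_n=eff_n, alpha=alpha)
    est.method = f"hajek+{glm['method']}/{ci_method}"
    for lv in exposed_levels:
        ate, se, ci, _ = risk_difference_ate(
            y, level, w, clusters, (lv, reference), alpha=alpha
        )
        col = f"exposure[{lv}]"
        rr = glm["rr"][col]
        rr_ci = glm["rr_ci"][col]
        if ci_method == "cluster-bootstrap":
            ci = cluster_bootstrap_ci(
                y, level, w, clusters, (lv, reference), "risk_difference",
                reps=bootstrap_reps, seed=seed, alpha=alpha,
            )
            rr_ci = cluster_bootstrap_ci(
                y, level, w, clusters, (lv, reference), "risk_ratio",
                reps=bootstrap_reps, seed=seed, alpha=alpha,
            )
        est.contrasts.append(
            ContrastEstimate(
                exposed=lv,
                reference=reference,
                risk_exposed=risks[lv],
                risk_reference=risks[reference],
                risk_difference=ate,
                rd_se=se,
                rd_ci=ci,
                risk_ratio=rr,
                log_rr_se=float(glm["bse"][col]),
                rr_ci=rr_ci,
                method=est.method,
            )
        )
    return est
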