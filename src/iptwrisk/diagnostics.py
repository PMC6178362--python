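"""Pseudo-population diagnostics: covariate balance and weight summaries.

Weighting is supposed to produce a pseudo-population in which exposure is
independent of the modelled confounders; the standardized mean difference
(SMD) before and after weighting is the conventional check. The SMD numerator
uses (weighted) group means; the denominator is the pooled *unweighted* SD,
so the yardstick stays fixed across weighting schemes. Stabilized weights
should also average ~1, which :func:`weight_summary` reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CovariateSpec

__all__ = [
    "DiagnosticsError",
    "BalanceTable",
    "standardized_mean_difference",
    "balance_table",
    "weight_summary",
    "BALANCE_THRESHOLD",
]

#: conventional |SMD| threshold above which imbalance is flagged
BALANCE_THRESHOLD = 0.1


class DiagnosticsError(ValueError):
    """Invalid input to a balance diagnostic."""


@dataclass
class BalanceTable:
    """SMDs per covariate and exposure contrast, before and after weighting."""

    table: pd.DataFrame
    threshold: float = BALANCE_THRESHOLD

    @property
    def flagged(self) -> pd.DataFrame:
        """Rows whose weighted |SMD| exceeds the threshold."""
        return self.table[self.table["smd_weighted"].abs() > self.threshold]

    def love_plot_data(self) -> pd.DataFrame:
        """(covariate, smd_before, smd_after) for external plotting."""
        return self.table.rename(
            columns={"smd_unweighted": "smd_before", "smd_weighted": "smd_after"}
        )[["covariate", "contrast", "smd_before", "smd_after"]]


def standardized_mean_difference(x, level, w=None, binary: bool | None = None) -> float:
    """SMD between two groups: exposed-minus-reference mean difference over
    the pooled unweighted SD.

    ``level`` is a boolean/0-1 vector with True (1) marking the exposed
    group; the sign convention is exposed minus reference. Binary covariates
    use sqrt((p1(1-p1)+p0(1-p0))/2) with unweighted proportions as the
    denominator (``binary`` overrides the autodetection). Raises on a zero
    pooled SD.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(level).astype(bool)
    if g.all() or not g.any():
        raise DiagnosticsError("both groups must be non-empty")
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if binary is None:
        binary = set(np.unique(x)) <= {0.0, 1.0}
    m1 = np.average(x[g], weights=w[g])
    m0 = np.average(x[~g], weights=w[~g])
    if binary:
        p1, p0 = x[g].mean(), x[~g].mean()
        denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2)
    else:
        s1 = x[g].std(ddof=1)
        s0 = x[~g].std(ddof=1)
        denom = np.sqrt((s1**2 + s0**2) / 2)
    if denom == 0:
        raise DiagnosticsError("zero pooled SD: SMD undefined")
    return float((m1 - m0) / denom)


def _covariate_frame(cohort: pd.DataFrame, spec: CovariateSpec) -> pd.DataFrame:
    """Numeric balance columns for every covariate in the model spec.

    Continuous terms contribute the raw covariate (a spline is still one
    covariate for balance purposes); dummies contribute one 0/1 column per
    non-reference level; boolean fields are coerced to 0/1.
    """
    out = {}
    for term in spec.terms:
        col = cohort[term.field]
        if term.transform == "dummy":
            levels = [lv for lv in col.unique() if lv != term.reference]
            for lv in sorted(map(str, levels)):
                out[f"{term.field}[{lv}]"] = (col.astype(str) == lv).astype(float)
        else:
            out[term.field] = col.astype(float)
    return pd.DataFrame(out, index=cohort.index)


def balance_table(
    cohort: pd.DataFrame,
    level,
    w,
    spec: CovariateSpec,
    reference: str | int | bool = None,
    threshold: float = BALANCE_THRESHOLD,
) -> BalanceTable:
    """SMD before/after weighting for every covariate in ``spec``.

    Multi-level exposures report every non-reference level vs the reference.
    ``reference`` defaults to False/0 for a binary level vector and must be
    given explicitly for a multi-level one.
    """
    level = np.asarray(level, dtype=object)
    w = np.asarray(w, dtype=float)
    levels = list(dict.fromkeys(level))
    if reference is None:
        if len(levels) != 2:
            raise DiagnosticsError("reference level required for multi-level exposure")
        reference = False if set(levels) <= {False, True} else 0
    others = [lv for lv in levels if lv != reference]
    frame = _covariate_frame(cohort, spec)
    rows = []
    for lv in others:
        mask = (level == lv) | (level == reference)
        g = level[mask] == lv
        for cov in frame.columns:
            x = frame[cov].to_numpy()[mask]
            rows.append(
                {
                    "covariate": cov,
                    "contrast": f"{lv} vs {reference}",
                    "smd_unweighted": standardized_mean_difference(x, g),
                    "smd_weighted": standardized_mean_difference(x, g, w[mask]),
                }
            )
    return BalanceTable(table=pd.DataFrame(rows), threshold=threshold)


def weight_summary(w, n_clipped: int = 0, n_truncated: int = 0) -> dict:
    """Descriptive summary of a weight vector.

    The mean is the headline stabilization check (should be ~1 for
    stabilized weights under correct model specification).
    """
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise DiagnosticsError("empty weight vector")
    return {
        "mean": float(w.mean()),
        "sd": float(w.std(ddof=1)) if w.size > 1 else 0.0,
        "min": float(w.min()),
        "max": float(w.max()),
        "p1": float(np.percentile(w, 1)),
        "p99": float(np.percentile(w, 99)),
        "n": int(w.size),
        "n_clipped": int(n_clipped),
        "n_truncated": int(n_truncated),
    }
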