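"""Stabilized inverse-probability weights.

The treatment weight for a record at exposure level *a* is the marginal
probability of *a* divided by the record's conditional (propensity)
probability of *a*; for a binary exposure this is Pr(A=1)/Pr(A=1|L) for the
exposed and (1-Pr(A=1))/(1-Pr(A=1|L)) for the unexposed. The censoring weight
is the marginal probability of remaining under observation divided by the
conditional probability given baseline covariates. Their product is the
weight used in the outcome analysis; it creates a pseudo-population in which
exposure is independent of the modelled confounders and loss to follow-up is
ignorable. Stabilized weights have mean ~1 when the models are correctly
specified, which :func:`iptwrisk.diagnostics.weight_summary` checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "WeightError",
    "WeightSet",
    "stabilized_exposure_weights",
    "stabilized_censoring_weights",
    "combine_and_truncate",
]


class WeightError(ValueError):
    """Invalid probability or shape input to weight construction."""


@dataclass
class WeightSet:
    """Per-record stabilized weights.

    ``sw_censoring`` is defined for every record but consumed only for the
    uncensored; ``combined`` is the elementwise product used in the outcome
    analysis. ``truncation`` records the percentile bounds applied (None if
    none) and ``n_truncated`` how many combined weights they touched.
    """

    sw_treatment: np.ndarray
    sw_censoring: np.ndarray
    combined: np.ndarray
    truncation: tuple[float, float] | None = None
    n_truncated: int = 0

    def __post_init__(self):
        for name in ("sw_treatment", "sw_censoring", "combined"):
            w = getattr(self, name)
            if not (np.isfinite(w).all() and (w > 0).all()):
                raise WeightError(f"{name} contains non-positive or non-finite values")


def _check_probs(p: np.ndarray, what: str) -> None:
    if not np.isfinite(p).all() or (p <= 0).any() or (p >= 1).any():
        raise WeightError(f"{what} must lie strictly inside (0, 1)")


def stabilized_exposure_weights(
    level: Sequence,
    marginal: Mapping | float,
    conditional: Sequence[float],
) -> np.ndarray:
    """Stabilized treatment weight: marginal(level_i) / conditional_i.

    ``level`` holds each record's observed exposure level; ``marginal`` maps
    level -> marginal probability (a scalar is accepted for a binary 0/1
    exposure and interpreted as Pr(A=1)); ``conditional`` is the record's
    propensity of its *own* observed level. The same formula covers the
    binary and the three-level analysis.
    """
    level = np.asarray(level, dtype=object)
    cond = np.asarray(conditional, dtype=float)
    if level.shape != cond.shape:
        raise WeightError("level and conditional must have equal length")
    if isinstance(marginal, Mapping):
        missing = set(level) - set(marginal)
        if missing:
            raise WeightError(f"no marginal probability for level(s) {sorted(map(str, missing))}")
        marg = np.array([marginal[v] for v in level], dtype=float)
    else:
        p1 = float(marginal)
        _check_probs(np.array([p1]), "marginal probability")
        marg = np.where(level.astype(float) == 1.0, p1, 1.0 - p1)
    _check_probs(marg, "marginal probabilities")
    _check_probs(cond, "conditional probabilities")
    return marg / cond


def stabilized_censoring_weights(
    observed: Sequence[bool],
    marginal_uncensored: float,
    conditional_uncensored: Sequence[float],
) -> np.ndarray:
    """Stabilized censoring weight: Pr(uncensored) / Pr(uncensored | L).

    Returned for every record; the analysis consumes it only for records with
    ``observed`` true. A cohort with no censoring (both probabilities 1 after
    clipping) yields weights of exactly 1.
    """
    obs = np.asarray(observed, dtype=bool)
    cond = np.asarray(conditional_uncensored, dtype=float)
    if obs.shape != cond.shape:
        raise WeightError("observed and conditional must have equal length")
    marg = float(marginal_uncensored)
    if not 0 < marg <= 1:
        raise WeightError("marginal uncensored probability must be in (0, 1]")
    if not (np.isfinite(cond).all() and (cond > 0).all() and (cond <= 1).all()):
        raise WeightError("conditional uncensored probabilities must be in (0, 1]")
    return marg / cond


def combine_and_truncate(
    sw_t: Sequence[float],
    sw_c: Sequence[float],
    truncation: tuple[float, float] | None = None,
) -> WeightSet:
    """Combined weight = treatment weight x censoring weight.

    ``truncation``, if given, is a percentile pair (e.g. ``(1, 99)``): the
    combined weights are winsorized at those percentiles and the number of
    affected records recorded. The default is no truncation.
    """
    sw_t = np.asarray(sw_t, dtype=float)
    sw_c = np.asarray(sw_c, dtype=float)
    if sw_t.shape != sw_c.shape:
        raise WeightError("treatment and censoring weights must have equal length")
    combined = sw_t * sw_c
    n_trunc = 0
    if truncation is not None:
        lo_p, hi_p = truncation
        if not (0 <= lo_p < hi_p <= 100):
            raise WeightError(f"invalid truncation percentiles {truncation}")
        lo, hi = np.percentile(combined, [lo_p, hi_p])
        n_trunc = int(((combined < lo) | (combined > hi)).sum())
        combined = np.clip(combined, lo, hi)
    return WeightSet(
        sw_treatment=sw_t,
        sw_censoring=sw_c,
        combined=combined,
        truncation=truncation,
        n_truncated=n_trunc,
    )
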