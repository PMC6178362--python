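"""Exposure and censoring probability models.

The propensity score is Pr(exposure | confounders). The binary analysis
(pre-hypertension vs normal BP) uses a logistic regression; the three-level
analysis (optimal / normal / high-normal) uses a baseline-category multinomial
logit; the censoring model is a logistic regression for remaining under
observation. Estimation is unpenalized maximum likelihood via statsmodels
(IRLS/Newton), wrapped here to enforce the contracts the weighting pipeline
depends on: rank and outcome-variation checks with informative errors, a
recorded convergence flag instead of an exception at the iteration cap, a
separation warning, and clipped predicted probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PropensityError",
    "PropensityFit",
    "fit_binary_logistic",
    "fit_multinomial",
    "predict_probabilities",
]

logger = logging.getLogger(__name__)

#: default clipping bound for predicted probabilities (protects weight division)
DEFAULT_CLIP = 1e-6

#: |coefficient| on the logit scale beyond which separation is flagged
SEPARATION_BOUND = 30.0

MAX_ITER = 100
SCORE_TOL = 1e-8


class PropensityError(ValueError):
    """Invalid input to a propensity model fit."""


@dataclass
class PropensityFit:
    """A fitted exposure or censoring model.

    For ``kind == "binary"`` ``params`` has one column; for multinomial one
    column per non-reference level. ``fitted`` holds in-sample probabilities:
    a vector (binary) or an (n, n_levels) matrix with columns in ``levels``
    order (reference first).
    """

    kind: str
    params: pd.DataFrame
    columns: list[str]
    levels: list[str]
    reference: str
    converged: bool
    n_iterations: int
    log_likelihood: float
    fitted: np.ndarray
    warnings: list[str] = field(default_factory=list)
    n_clipped: int = 0

    def coefficient_table(self) -> pd.DataFrame:
        """Plain coefficient table (one row per design column)."""
        return self.params.copy()


def _check_design(X: pd.DataFrame) -> np.ndarray:
    Xa = np.asarray(X, dtype=float)
    if not np.isfinite(Xa).all():
        raise PropensityError("design matrix contains non-finite values")
    n, p = Xa.shape
    if n <= p:
        raise PropensityError(f"more columns ({p}) than informative rows ({n})")
    # pivoted QR exposes which columns are collinear
    scale = np.linalg.norm(Xa, axis=0)
    scale[scale == 0] = 1.0
    from scipy.linalg import qr

    _, R, piv = qr(Xa / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n, p) * np.finfo(float).eps * 100
    bad = piv[diag < tol]
    if len(bad):
        names = [X.columns[j] for j in sorted(bad)]
        raise PropensityError(f"design matrix is rank deficient; collinear columns: {names}")
    return Xa


def _postfit_warnings(fit: PropensityFit) -> None:
    big = np.abs(fit.params.to_numpy()).max()
    if big > SEPARATION_BOUND:
        msg = (
            f"possible complete separation: max |coefficient| = {big:.1f} "
            f"exceeds {SEPARATION_BOUND} on the logit scale"
        )
        fit.warnings.append(msg)
        logger.warning(msg)
    if not fit.converged:
        msg = f"optimizer did not converge within {MAX_ITER} iterations"
        fit.warnings.append(msg)
        logger.warning(msg)


def fit_binary_logistic(
    X: pd.DataFrame,
    y: Sequence,
    obs_weights: Sequence | None = None,
) -> PropensityFit:
    """Weighted maximum-likelihood logistic regression.

    ``obs_weights`` multiply each record's log-likelihood contribution
    (uniform if omitted); a weighted fit with integer weights equals the
    unweighted fit on row-expanded data. Degenerate outcomes and
    rank-deficient designs raise; hitting the iteration cap sets
    ``converged=False`` on the returned fit instead of raising.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise PropensityError("y must be 0/1")
    if y.min() == y.max():
        raise PropensityError("no outcome variation: y is constant")
    Xa = _check_design(X)
    w = None if obs_weights is None else np.asarray(obs_weights, dtype=float)
    if w is not None and (w <= 0).any():
        raise PropensityError("observation weights must be positive")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xa, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(maxiter=MAX_ITER, tol=SCORE_TOL)

    params = pd.DataFrame({"exposed": res.params}, index=list(X.columns))
    fit = PropensityFit(
        kind="binary",
        params=params,
        columns=list(X.columns),
        levels=["unexposed", "exposed"],
        reference="unexposed",
        converged=bool(getattr(res, "converged", True)),
        n_iterations=len(res.fit_history.get("deviance", [])) if hasattr(res, "fit_history") else -1,
        log_likelihood=float(res.llf),
        fitted=np.asarray(res.fittedvalues, dtype=float),
    )
    _postfit_warnings(fit)
    return fit


def fit_multinomial(
    X: pd.DataFrame,
    y: Sequence,
    reference: str,
    levels: Sequence[str] | None = None,
) -> PropensityFit:
    """Baseline-category multinomial logit for a multi-level exposure.

    ``y`` is a vector of level labels; ``reference`` fixes the baseline
    category. Every level must be present. Returns per-record probabilities
    for all levels (columns ordered reference first, then remaining levels
    in ``levels`` order if given, else first appearance).
    """
    y = np.asarray(y, dtype=object)
    observed = list(dict.fromkeys(y)) if levels is None else list(levels)
    if reference not in observed:
        raise PropensityError(f"reference level {reference!r} absent from y")
    if set(np.unique(y.astype(str))) - set(map(str, observed)):
        raise PropensityError("y contains levels not listed in `levels`")
    levels = [reference] + [lv for lv in observed if lv != reference]
    if len(levels) < 2:
        raise PropensityError("need at least two exposure levels")
    counts = {lv: int((y == lv).sum()) for lv in levels}
    empty = [lv for lv, c in counts.items() if c == 0]
    if empty:
        raise PropensityError(f"exposure level(s) with no records: {empty}")
    Xa = _check_design(X)
    codes = np.array([levels.index(v) for v in y])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes, Xa)
        res = model.fit(method="newton", maxiter=MAX_ITER, gtol=SCORE_TOL, disp=0)

    params = pd.DataFrame(
        np.asarray(res.params), index=list(X.columns), columns=levels[1:]
    )
    probs = np.asarray(res.predict(Xa), dtype=float)  # columns in code order
    fit = PropensityFit(
        kind="multinomial",
        params=params,
        columns=list(X.columns),
        levels=levels,
        reference=reference,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iterations=int(res.mle_retvals.get("iterations", -1)),
        log_likelihood=float(res.llf),
        fitted=probs,
    )
    _postfit_warnings(fit)
    return fit


def predict_probabilities(
    fit: PropensityFit, X: pd.DataFrame, clip: float = DEFAULT_CLIP
) -> np.ndarray:
    """Predicted probabilities from a fitted model, clipped to
    ``[clip, 1 - clip]``.

    Binary fits return the probability of the non-reference level; multinomial
    fits return an (n, n_levels) matrix with columns in ``fit.levels`` order.
    Clipping events are counted on the fit and logged.
    """
    if list(X.columns) != fit.columns:
        raise PropensityError(
            f"design columns {list(X.columns)} do not match fit columns {fit.columns}"
        )
    Xa = np.asarray(X, dtype=float)
    if fit.kind == "binary":
        eta = Xa @ fit.params.to_numpy()[:, 0]
        p = 1.0 / (1.0 + np.exp(-eta))
    else:
        eta = Xa @ fit.params.to_numpy()  # (n, k-1)
        eta = np.column_stack([np.zeros(len(Xa)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        expeta = np.exp(eta)
        p = expeta / expeta.sum(axis=1, keepdims=True)
    clipped = (p < clip) | (p > 1 - clip)
    n_clipped = int(clipped.sum())
    if n_clipped:
        fit.n_clipped += n_clipped
        logger.info("clipped %d predicted probabilities to [%g, %g]", n_clipped, clip, 1 - clip)
    p = np.clip(p, clip, 1 - clip)
    if fit.kind == "multinomial":
        p = p / p.sum(axis=1, keepdims=True)
    return p
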