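"""Model matrices for the exposure, censoring and outcome models.

Supports the three transforms the analysis needs — linear terms, a 3-knot
restricted cubic spline (Harrell's truncated-power basis), and reference-level
dummy coding — plus pairwise interactions, with a deterministic column order.
There is deliberately no general formula language; covariate specifications
are explicit, serializable objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ECONOMIC_LEVELS, MARITAL_LEVELS, SEX_LEVELS

__all__ = [
    "Term",
    "CovariateSpec",
    "DesignInfo",
    "DesignError",
    "rcs_basis",
    "auto_knots",
    "build_design",
    "default_exposure_spec",
    "default_censoring_spec",
]

# canonical level orders for the cohort's categorical fields; other fields
# fall back to sorted observed levels
_CANONICAL_LEVELS = {
    "sex": list(SEX_LEVELS),
    "marital_status": list(MARITAL_LEVELS),
    "economic_status": list(ECONOMIC_LEVELS),
}


class DesignError(ValueError):
    """Invalid covariate specification or design-matrix input."""


@dataclass(frozen=True)
class Term:
    """One model term: a source field and its transform.

    transform is one of ``linear`` (numeric/boolean as-is), ``rcs3``
    (3-knot restricted cubic spline, two columns), or ``dummy``
    (reference-level coding; ``reference`` names the dropped level).
    """

    field: str
    transform: str = "linear"
    reference: str | None = None

    def __post_init__(self):
        if self.transform not in ("linear", "rcs3", "dummy"):
            raise DesignError(f"unknown transform {self.transform!r}")
        if self.transform == "dummy" and self.reference is None:
            raise DesignError(f"dummy term {self.field!r} needs a reference level")


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered covariate specification for one model."""

    terms: tuple[Term, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        names = [t.field for t in self.terms]
        if len(set(names)) != len(names):
            raise DesignError("duplicate term fields in spec")
        for a, b in self.interactions:
            for f in (a, b):
                if f not in names:
                    raise DesignError(
                        f"interaction member {f!r} is not a main term"
                    )

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"field": t.field, "transform": t.transform, "reference": t.reference}
                for t in self.terms
            ],
            "interactions": [list(p) for p in self.interactions],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSpec":
        terms = tuple(
            Term(t["field"], t.get("transform", "linear"), t.get("reference"))
            for t in d["terms"]
        )
        inter = tuple(tuple(p) for p in d.get("interactions", []))
        return cls(terms=terms, interactions=inter)


@dataclass
class DesignInfo:
    """Fitted design metadata needed to rebuild the matrix at predict time."""

    spec: CovariateSpec
    columns: list[str] = field(default_factory=list)
    knots: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    levels: dict[str, list[str]] = field(default_factory=dict)


def auto_knots(x: np.ndarray) -> tuple[float, float, float]:
    """Place 3 spline knots at the 0.10/0.50/0.90 quantiles of ``x``."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 10:
        raise DesignError("need >= 10 distinct values for automatic knot placement")
    k = tuple(float(q) for q in np.quantile(x, (0.10, 0.50, 0.90)))
    if not (k[0] < k[1] < k[2]):
        raise DesignError(f"automatic knots are not strictly increasing: {k}")
    return k


def rcs_basis(x, knots: Sequence[float] | None = None):
    """Restricted cubic spline basis with 3 knots (2 columns).

    Column 1 is ``x`` itself; column 2 is the restricted truncated-power
    cubic term, normalized by ``(k3 - k1)**2`` so both columns share x's
    units::

        ((x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2) + (x-k3)+^3 (k2-k1)/(k3-k2))
        / (k3-k1)^2

    The restriction makes the fitted curve linear below the first and above
    the last knot. Returns ``(basis, knots)`` with basis of shape (n, 2).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = auto_knots(x)
    k1, k2, k3 = (float(k) for k in knots)
    if not (k1 < k2 < k3):
        raise DesignError(f"knots must be strictly increasing, got {knots}")

    def p3(u):
        return np.clip(u, 0.0, None) ** 3

    nonlin = (
        p3(x - k1)
        - p3(x - k2) * (k3 - k1) / (k3 - k2)
        + p3(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return np.column_stack([x, nonlin]), (k1, k2, k3)


def _term_columns(df: pd.DataFrame, term: Term, info: DesignInfo, fitting: bool):
    """Column names and values for one main term."""
    f = term.field
    if f not in df.columns:
        raise DesignError(f"field {f!r} not present in cohort")
    if term.transform == "linear":
        vals = df[f].to_numpy(dtype=float)
        return [f], [vals]
    if term.transform == "rcs3":
        x = df[f].to_numpy(dtype=float)
        if fitting:
            basis, knots = rcs_basis(x)
            info.knots[f] = knots
        else:
            basis, _ = rcs_basis(x, info.knots[f])
        return [f, f + "_rcs1"], [basis[:, 0], basis[:, 1]]
    # dummy
    vals = df[f].astype(object)
    if fitting:
        observed = set(vals.unique())
        canonical = _CANONICAL_LEVELS.get(f)
        if canonical is None:
            canonical = sorted(observed)
        levels = [lv for lv in canonical if lv != term.reference]
        unknown = observed - set(canonical) - {term.reference}
        if unknown:
            raise DesignError(f"field {f!r}: unexpected level(s) {sorted(unknown)}")
        info.levels[f] = levels
    else:
        levels = info.levels[f]
        unknown = set(vals.unique()) - set(levels) - {term.reference}
        if unknown:
            raise DesignError(
                f"field {f!r}: unseen level(s) {sorted(unknown)} at predict time"
            )
    names, cols = [], []
    for lv in levels:
        names.append(f"{f}[{lv}]")
        cols.append((vals == lv).to_numpy(dtype=float))
    return names, cols


def build_design(
    cohort: pd.DataFrame, spec: CovariateSpec, info: DesignInfo | None = None
):
    """Build the model matrix for ``spec`` on ``cohort``.

    The intercept column is always first, then main terms in spec order,
    then interaction columns (elementwise products of the named main-term
    columns). Pass the :class:`DesignInfo` returned from the fitting call to
    rebuild the same matrix on new data (same knots and dummy levels; an
    unseen categorical level raises).

    Returns ``(X, info)`` with ``X`` a :class:`pandas.DataFrame`.
    """
    fitting = info is None
    if fitting:
        info = DesignInfo(spec=spec)
    names: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones(len(cohort))]
    by_field: dict[str, list[int]] = {}
    for term in spec.terms:
        tnames, tcols = _term_columns(cohort, term, info, fitting)
        by_field[term.field] = list(range(len(names), len(names) + len(tnames)))
        names.extend(tnames)
        cols.extend(tcols)
    for a, b in spec.interactions:
        for ia in by_field[a]:
            for ib in by_field[b]:
                names.append(f"{names[ia]}:{names[ib]}")
                cols.append(cols[ia] * cols[ib])
    X = pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(cohort), 0)),
                     columns=names, index=cohort.index)
    if fitting:
        info.columns = names
    elif names != info.columns:
        raise DesignError("rebuilt design columns do not match fitted design")
    return X, info


def default_exposure_spec(interaction: bool = True) -> CovariateSpec:
    """Exposure-model covariates: BMI, age (3-knot spline) and education as
    continuous; marital status, sex, economic status (reference = high) and
    smoking as categorical; optional BMI x education interaction."""
    terms = (
        Term("bmi"),
        Term("age", "rcs3"),
        Term("education_years"),
        Term("sex", "dummy", reference="female"),
        Term("marital_status", "dummy", reference="other"),
        Term("economic_status", "dummy", reference="high"),
        Term("smoking"),
    )
    inter = (("bmi", "education_years"),) if interaction else ()
    return CovariateSpec(terms=terms, interactions=inter)


def default_censoring_spec() -> CovariateSpec:
    """Censoring-model covariates: the exposure spec without the interaction."""
    return default_exposure_spec(interaction=False)
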