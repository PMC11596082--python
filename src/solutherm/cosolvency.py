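"""The van't Hoff-Yalkowsky-Roseman hybrid cosolvency model.

The Yalkowsky-Roseman log-linear rule expresses the log solubility in a
binary solvent blend as the mass-fraction-weighted mean of the pure-solvent
log solubilities. Writing each pure-solvent solubility with a two-parameter
van't Hoff line ln x_i = a_i + m_i / T gives the four-parameter hybrid

    ln x(w1, T) = w1 (a1 + m1/T) + (1 - w1)(a2 + m2/T),

whose coefficients need only the two extreme-temperature solubilities in
each pure solvent — four measurements predict the whole composition x
temperature grid.

Model quality is summarised by the mean relative deviation

    MRD = (100/N) sum |x_E - x_C| / x_ref

with the experimental value x_E as the reference denominator by default
(``reference="calculated"`` divides by the model value instead; a signed
mean is also reported, where cancellation is informative), and by r^2 of
the predicted-vs-experimental regression on the solubility scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .grid import SolubilityGrid
from .vanthoff import fit_vant_hoff, harmonic_mean_temperature

__all__ = [
    "VhYrModel",
    "ValidationReport",
    "fit_two_point",
    "build_model",
    "predict",
    "validate",
]


@dataclass(frozen=True)
class VhYrModel:
    """Coefficients of the four-parameter hybrid: intercept/slope per solvent.

    Index 1 is the solvent whose term carries weight w1; index 2 carries
    (1 - w1). Slopes are in K; intercepts dimensionless.
    """

    a1: float
    m1: float
    a2: float
    m2: float

    def __post_init__(self) -> None:
        for name in ("a1", "m1", "a2", "m2"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"coefficient {name} must be finite")

    def predict(self, w1, T, extrapolate: bool = False):
        return predict(self, w1, T, extrapolate=extrapolate)


@dataclass(frozen=True)
class ValidationReport:
    """Model-vs-experiment summary over a grid.

    ``mrd`` is the mean absolute relative deviation in percent;
    ``mrd_signed`` keeps the sign of (x_E - x_C)/x_ref. ``residuals`` are
    the per-point signed relative deviations in percent, grid order.
    """

    mrd: float
    mrd_signed: float
    r2: float
    n: int
    residuals: np.ndarray
    reference: str = "experimental"


def fit_two_point(
    x_cold: float, x_hot: float, T_cold: float, T_hot: float
) -> tuple[float, float]:
    """Exact van't Hoff line ln x = a + m/T through two points.

    Returns (a, m). Degenerate if the two temperatures coincide.
    """
    if x_cold <= 0 or x_hot <= 0:
        raise DomainError("solubilities must be positive")
    if T_cold <= 0 or T_hot <= 0:
        raise DomainError("temperatures must be positive (K)")
    if T_cold == T_hot:
        raise DomainError("two-point fit needs two distinct temperatures")
    m = (math.log(x_hot) - math.log(x_cold)) / (1.0 / T_hot - 1.0 / T_cold)
    a = math.log(x_cold) - m / T_cold
    return a, m


def build_model(grid: SolubilityGrid, fit: str = "two-point") -> VhYrModel:
    """Fit the hybrid model from a grid's pure-solvent columns.

    ``fit="two-point"`` (default) uses only the extreme-temperature cells of
    each pure solvent — four data in all. ``fit="all-temps"`` instead runs
    the full van't Hoff regression over every temperature of each pure
    column. Solvent 1 coefficients come from the w1 = 1 column, solvent 2
    from w1 = 0.
    """
    comps = grid.compositions
    for endpoint in (0.0, 1.0):
        if not np.any(comps == endpoint):
            raise InsufficientDataError(
                f"grid lacks the pure-solvent column w1={endpoint}"
            )
    if fit not in ("two-point", "all-temps"):
        raise ValueError(f"unknown fit mode {fit!r}")

    coeffs = {}
    for idx, w in ((1, 1.0), (2, 0.0)):
        col = grid.column(w)
        if fit == "two-point":
            cold, hot = col[0], col[-1]
            if cold.T == hot.T:
                raise InsufficientDataError(
                    f"w1={w} column has a single temperature"
                )
            a, m = fit_two_point(cold.x3, hot.x3, cold.T, hot.T)
        else:
            Thm = harmonic_mean_temperature([p.T for p in col])
            vf = fit_vant_hoff(col, Thm)
            # recast the mean-centered line to the plain a + m/T form
            a, m = vf.a - vf.m / Thm, vf.m
        coeffs[idx] = (a, m)
    return VhYrModel(
        a1=coeffs[1][0], m1=coeffs[1][1], a2=coeffs[2][0], m2=coeffs[2][1]
    )


def predict(model: VhYrModel, w1, T, extrapolate: bool = False):
    """Predicted mole-fraction solubility at (w1, T); vectorized.

    Log-linear in w1 by construction; ``extrapolate`` permits w1 outside
    [0, 1].
    """
    w1 = np.asarray(w1, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperatures must be positive (K)")
    if not extrapolate and (np.any(w1 < 0) or np.any(w1 > 1)):
        raise DomainError(
            "w1 outside [0, 1]; pass extrapolate=True to override"
        )
    ln_x = w1 * (model.a1 + model.m1 / T) + (1.0 - w1) * (
        model.a2 + model.m2 / T
    )
    out = np.exp(ln_x)
    return float(out) if out.ndim == 0 else out


def deviation_summary(
    x_exp, x_calc, reference: str = "experimental"
) -> ValidationReport:
    """Summarise experimental-vs-calculated solubilities.

    ``reference`` selects the denominator of the relative deviations:
    ``"experimental"`` divides by x_E, ``"calculated"`` by the model value
    x_C. r^2 is computed on the solubility scale (not its log), matching the
    usual experimental-vs-predicted parity plot.
    """
    if reference not in ("experimental", "calculated"):
        raise ValueError(f"unknown reference {reference!r}")
    xE = np.asarray(x_exp, dtype=float)
    xC = np.asarray(x_calc, dtype=float)
    if xE.size == 0:
        raise DomainError("no points to validate against")
    denom = xE if reference == "experimental" else xC
    rel = 100.0 * (xE - xC) / denom
    if len(xE) >= 2 and np.ptp(xE) > 0:
        r2 = float(stats.linregress(xE, xC).rvalue) ** 2
    else:
        r2 = 1.0 if np.allclose(xE, xC) else 0.0
    return ValidationReport(
        mrd=float(np.mean(np.abs(rel))),
        mrd_signed=float(np.mean(rel)),
        r2=r2,
        n=len(xE),
        residuals=rel,
        reference=reference,
    )


def validate(
    model: VhYrModel,
    grid: SolubilityGrid,
    reference: str = "experimental",
) -> ValidationReport:
    """Score the model against every point of a grid (see
    :func:`deviation_summary` for the conventions)."""
    xE = np.asarray([p.x3 for p in grid.points])
    w1 = np.asarray([p.w1 for p in grid.points])
    T = np.asarray([p.T for p in grid.points])
    xC = predict(model, w1, T)
    return deviation_summary(xE, xC, reference=reference)
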