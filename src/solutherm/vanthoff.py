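"""Mean-centered van't Hoff regression and apparent solution thermodynamics.

At each solvent composition, ln x3 is regressed on (1/T - 1/Thm), where Thm
is the harmonic mean of the study temperatures (Krug's mean-centering). The
slope m and intercept a then give the apparent standard functions at Thm:

    dH_soln = -R m            (J mol^-1; reported in kJ mol^-1)
    dG_soln = -R Thm a
    dS_soln = (dH_soln - dG_soln) / Thm

Mean-centering makes the slope and intercept estimates orthogonal, so their
standard errors propagate independently:

    u(dH) = R se(m),   u(dG) = R Thm se(a),
    u(dS) = sqrt(u(dH)^2 + u(dG)^2) / Thm.

The relative weights of enthalpy and entropy in the Gibbs energy are the
zeta partition: zeta_H = |dH| / (|dH| + |T dS|), zeta_TS = 1 - zeta_H.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R
from .exceptions import DomainError, GridValidationError, InsufficientDataError
from .grid import SolubilityGrid, SolubilityPoint, harmonic_mean_temperature

__all__ = [
    "VantHoffFit",
    "ThermoFunctions",
    "SolutionAnalysis",
    "fit_vant_hoff",
    "solution_thermodynamics",
    "zeta_partition",
    "analyze_grid",
]


@dataclass(frozen=True)
class VantHoffFit:
    """OLS fit of ln x3 = a + m (1/T - 1/Thm) at one composition."""

    w1: float
    m: float  # slope, K
    a: float  # intercept = ln x3 at Thm
    se_m: float
    se_a: float
    r2: float
    n: int
    Thm: float


@dataclass(frozen=True)
class ThermoFunctions:
    """Standard thermodynamic functions at Thm for one process.

    Energies (dG, dH, TdS) in kJ mol^-1; dS in J mol^-1 K^-1. ``process``
    is one of ``"solution"``, ``"ideal"`` or ``"mixing"``. The zeta fields
    are the normalized absolute enthalpic/entropic contributions and are
    populated for the solution process (and on request for mixing).
    """

    dG: float
    dH: float
    dS: float
    TdS: float
    Thm: float
    process: str = "solution"
    w1: float | None = None
    zeta_H: float | None = None
    zeta_TS: float | None = None
    u_dG: float | None = None
    u_dH: float | None = None
    u_dS: float | None = None


def fit_vant_hoff(
    points: Sequence[SolubilityPoint] | Sequence[tuple[float, float]],
    Thm: float,
) -> VantHoffFit:
    """Fit the mean-centered van't Hoff line to one composition's data.

    ``points`` are either :class:`SolubilityPoint` objects (sharing one w1)
    or plain (T, x3) pairs. At least three distinct temperatures are
    required; a two-point construction is a different tool (see
    :mod:`solutherm.cosolvency`).
    """
    if points and isinstance(points[0], SolubilityPoint):
        w1s = {p.w1 for p in points}  # type: ignore[union-attr]
        if len(w1s) > 1:
            raise GridValidationError(
                f"points span several compositions: {sorted(w1s)}"
            )
        w1 = points[0].w1  # type: ignore[union-attr]
        T = np.asarray([p.T for p in points], dtype=float)  # type: ignore[union-attr]
        x3 = np.asarray([p.x3 for p in points], dtype=float)  # type: ignore[union-attr]
    else:
        w1 = float("nan")
        T = np.asarray([p[0] for p in points], dtype=float)
        x3 = np.asarray([p[1] for p in points], dtype=float)

    if len(np.unique(T)) != len(T):
        raise GridValidationError("duplicate temperatures in van't Hoff fit")
    if len(T) < 3:
        raise InsufficientDataError(
            f"need >= 3 temperatures for a van't Hoff fit, got {len(T)}"
        )
    if np.any(x3 <= 0):
        raise DomainError("all x3 must be positive to take logarithms")

    res = stats.linregress(1.0 / T - 1.0 / Thm, np.log(x3))
    return VantHoffFit(
        w1=w1,
        m=float(res.slope),
        a=float(res.intercept),
        se_m=float(res.stderr),
        se_a=float(res.intercept_stderr),
        r2=float(res.rvalue) ** 2,
        n=len(T),
        Thm=float(Thm),
    )


def zeta_partition(dH: float, TdS: float) -> tuple[float, float]:
    """Normalized absolute contributions of enthalpy and entropy.

    zeta_H = |dH| / (|dH| + |TdS|); zeta_TS is its complement. Undefined
    when both terms vanish.
    """
    denom = abs(dH) + abs(TdS)
    if denom == 0.0:
        raise DomainError("zeta partition undefined: dH and TdS both zero")
    zh = abs(dH) / denom
    return zh, 1.0 - zh


def solution_thermodynamics(fit: VantHoffFit) -> ThermoFunctions:
    """Apparent solution functions at Thm from a mean-centered fit."""
    Thm = fit.Thm
    dH = -R * fit.m / 1000.0  # kJ/mol
    dG = -R * Thm * fit.a / 1000.0
    TdS = dH - dG
    dS = TdS * 1000.0 / Thm  # J/mol/K
    u_dH = R * fit.se_m / 1000.0
    u_dG = R * Thm * fit.se_a / 1000.0
    u_dS = float(np.hypot(u_dH, u_dG)) * 1000.0 / Thm
    if dH == 0.0 and TdS == 0.0:
        zh = zts = None
    else:
        zh, zts = zeta_partition(dH, TdS)
    return ThermoFunctions(
        w1=fit.w1 if fit.w1 == fit.w1 else None,  # NaN -> None
        dG=dG,
        dH=dH,
        dS=dS,
        TdS=TdS,
        Thm=Thm,
        process="solution",
        zeta_H=zh,
        zeta_TS=zts,
        u_dG=u_dG,
        u_dH=u_dH,
        u_dS=u_dS,
    )


@dataclass
class SolutionAnalysis:
    """Per-composition van't Hoff fits and solution functions for a grid."""

    Thm: float
    fits: list[VantHoffFit]
    thermo: list[ThermoFunctions]

    def to_frame(self) -> pd.DataFrame:
        """Solution-thermodynamics table (one row per composition)."""
        return pd.DataFrame(
            {
                "w1": [t.w1 for t in self.thermo],
                "dG_kJ_mol": [t.dG for t in self.thermo],
                "u_dG": [t.u_dG for t in self.thermo],
                "dH_kJ_mol": [t.dH for t in self.thermo],
                "u_dH": [t.u_dH for t in self.thermo],
                "dS_J_mol_K": [t.dS for t in self.thermo],
                "u_dS": [t.u_dS for t in self.thermo],
                "TdS_kJ_mol": [t.TdS for t in self.thermo],
                "zeta_H": [t.zeta_H for t in self.thermo],
                "zeta_TS": [t.zeta_TS for t in self.thermo],
            }
        )


def analyze_grid(grid: SolubilityGrid) -> SolutionAnalysis:
    """Fit every composition of a rectangular grid and tabulate the
    solution thermodynamic functions at the grid's harmonic mean temperature.
    """
    if not grid.is_rectangular():
        raise GridValidationError(
            "grid is not rectangular; run validate_grid for details"
        )
    temps = grid.temperatures
    if len(temps) < 3:
        raise InsufficientDataError("need >= 3 temperature levels")
    Thm = harmonic_mean_temperature(temps)
    fits = [fit_vant_hoff(grid.column(w), Thm) for w in grid.compositions]
    thermo = [solution_thermodynamics(f) for f in fits]
    return SolutionAnalysis(Thm=Thm, fits=fits, thermo=thermo)
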