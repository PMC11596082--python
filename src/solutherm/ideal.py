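"""Ideal solubility from fusion properties and the solution = ideal + mixing
decomposition.

The ideal solubility of a crystalline solute below its melting point follows
from the hypothetical fusion-and-cooling cycle alone (no solute-solvent
interaction), with a heat-capacity correction:

    ln x_id(T) = -(dH_fus/R)(1/T - 1/Tm)
                 + (dCp/R)[(Tm - T)/T - ln(Tm/T)]

With dCp = 0 this is the plain van't Hoff fusion form; the default
approximates dCp by the fusion entropy dH_fus/Tm. The ideal process
functions at the harmonic mean temperature are

    dH_id = dH_fus - dCp (Tm - Thm),   dG_id = -R Thm ln x_id(Thm),
    dS_id = (dH_id - dG_id)/Thm,

and subtracting them from the apparent solution functions isolates the
mixing (solute-solvent interaction) contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

from .constants import R
from .exceptions import ConsistencyError, DomainError
from .grid import FusionProperties
from .vanthoff import SolutionAnalysis, ThermoFunctions, zeta_partition

__all__ = [
    "IdealThermo",
    "ideal_solubility",
    "ideal_thermodynamics",
    "mixing_functions",
    "mixing_table",
]


@dataclass(frozen=True)
class IdealThermo(ThermoFunctions):
    """Ideal-process functions at Thm, plus ln x_ideal(Thm)."""

    ln_x_ideal: float = float("nan")


def ideal_solubility(T: float, fusion: FusionProperties) -> float:
    """ln of the ideal mole-fraction solubility at temperature ``T``.

    Monotone increasing in T and exactly 0 at the melting point (the melt is
    its own ideal solution). Requires 0 < T <= Tm.
    """
    if T <= 0:
        raise DomainError("T must be positive (K)")
    if T > fusion.Tm:
        raise DomainError(
            f"T={T} K above the melting point Tm={fusion.Tm} K: "
            "the ideal-solubility model applies to the solid"
        )
    dH = fusion.dH_fus * 1000.0  # J/mol
    dCp = fusion.dCp_effective
    main = -(dH / R) * (1.0 / T - 1.0 / fusion.Tm)
    corr = (dCp / R) * ((fusion.Tm - T) / T - math.log(fusion.Tm / T))
    return main + corr


def ideal_thermodynamics(fusion: FusionProperties, Thm: float) -> IdealThermo:
    """Ideal-process thermodynamic functions at the reference temperature."""
    if not 0 < Thm <= fusion.Tm:
        raise DomainError("require 0 < Thm <= Tm")
    ln_x = ideal_solubility(Thm, fusion)
    dH = fusion.dH_fus - fusion.dCp_effective * (fusion.Tm - Thm) / 1000.0
    dG = -R * Thm * ln_x / 1000.0
    TdS = dH - dG
    dS = TdS * 1000.0 / Thm
    return IdealThermo(
        dG=dG,
        dH=dH,
        dS=dS,
        TdS=TdS,
        Thm=Thm,
        process="ideal",
        ln_x_ideal=ln_x,
    )


def mixing_functions(
    solution: ThermoFunctions,
    ideal: IdealThermo,
    include_zeta: bool = False,
) -> ThermoFunctions:
    """Mixing functions: solution minus ideal, component-wise.

    Uncertainties are carried over from the solution process; the ideal term
    is treated as exact (fusion-constant uncertainties, when known, are far
    smaller than the regression errors).
    """
    if abs(solution.Thm - ideal.Thm) > 1e-9:
        raise ConsistencyError(
            f"reference temperatures differ: {solution.Thm} vs {ideal.Thm}"
        )
    dG = solution.dG - ideal.dG
    dH = solution.dH - ideal.dH
    TdS = dH - dG
    dS = TdS * 1000.0 / solution.Thm
    zh = zts = None
    if include_zeta and not (dH == 0.0 and TdS == 0.0):
        zh, zts = zeta_partition(dH, TdS)
    return ThermoFunctions(
        w1=solution.w1,
        dG=dG,
        dH=dH,
        dS=dS,
        TdS=TdS,
        Thm=solution.Thm,
        process="mixing",
        zeta_H=zh,
        zeta_TS=zts,
        u_dG=solution.u_dG,
        u_dH=solution.u_dH,
        u_dS=solution.u_dS,
    )


def mixing_table(
    analysis: SolutionAnalysis, fusion: FusionProperties
) -> pd.DataFrame:
    """Mixing-functions table for every composition of an analyzed grid."""
    ideal = ideal_thermodynamics(fusion, analysis.Thm)
    rows = [mixing_functions(t, ideal) for t in analysis.thermo]
    return pd.DataFrame(
        {
            "w1": [t.w1 for t in rows],
            "dG_mix_kJ_mol": [t.dG for t in rows],
            "u_dG": [t.u_dG for t in rows],
            "dH_mix_kJ_mol": [t.dH for t in rows],
            "u_dH": [t.u_dH for t in rows],
            "dS_mix_J_mol_K": [t.dS for t in rows],
            "u_dS": [t.u_dS for t in rows],
            "TdS_mix_kJ_mol": [t.TdS for t in rows],
        }
    )
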