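"""Synthetic solubility grids with known ground truth.

The generator emulates the statistical structure the analysis assumes: at
each composition ln x3 is linear in 1/T, and across compositions ln x3 is
the mass-fraction-weighted blend of the two pure-solvent van't Hoff lines
(the log-linear rule), perturbed by multiplicative lognormal noise with unit
mean and a chosen coefficient of variation. Noise is additive on ln x3, the
scale on which all regressions operate.

Defaults mirror the sulfamerazine study design: a 21 x 9 grid (w1 = 0.00 to
1.00 in steps of 0.05; 278.15-318.15 K in steps of 5 K) around the
four-coefficient truth fitted from the pure-solvent endpoint cells, with a
2 % noise CV, commensurate with the relative standard uncertainties of the
measured table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import R
from .cosolvency import VhYrModel
from .exceptions import DomainError
from .grid import SolubilityGrid, SolubilityPoint
from .vanthoff import ThermoFunctions

__all__ = ["SyntheticSpec", "generate_grid", "ground_truth_thermo"]

#: Pure-solvent van't Hoff coefficients of the sulfamerazine MeCN/EtOH study
#: (two-point fits to the endpoint cells of the measured grid).
DEFAULT_TRUTH = VhYrModel(a1=5.086, m1=-3260.9, a2=4.664, m2=-3773.8)


def _default_w1_grid() -> list[float]:
    return [round(0.05 * i, 2) for i in range(21)]


def _default_T_grid() -> list[float]:
    return [278.15 + 5.0 * i for i in range(9)]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic grid: truth coefficients, design, noise, seed."""

    truth: VhYrModel = DEFAULT_TRUTH
    w1_grid: list[float] = field(default_factory=_default_w1_grid)
    T_grid: list[float] = field(default_factory=_default_T_grid)
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if not self.w1_grid or not self.T_grid:
            raise DomainError("composition and temperature grids must be non-empty")


def generate_grid(spec: SyntheticSpec) -> SolubilityGrid:
    """Draw one grid from the spec; identical seeds give identical grids.

    The lognormal factor has unit mean: ln eps ~ N(-s^2/2, s^2) with
    s^2 = ln(1 + cv^2). Raises if any generated solubility reaches 1
    (unphysical for a dilute-solution model).
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    t = spec.truth
    points = []
    for w in spec.w1_grid:
        for T in spec.T_grid:
            ln_x = w * (t.a1 + t.m1 / T) + (1.0 - w) * (t.a2 + t.m2 / T)
            if spec.noise_cv > 0:
                ln_x += rng.normal(-0.5 * sigma**2, sigma)
            x3 = math.exp(ln_x)
            if x3 >= 1.0:
                raise DomainError(
                    f"spec generates x3 >= 1 at (w1={w}, T={T}): "
                    "unphysical solubility"
                )
            points.append(SolubilityPoint(w1=w, T=T, x3=x3))
    return SolubilityGrid(points=points, labels=("synthetic 1", "synthetic 2"))


def ground_truth_thermo(spec: SyntheticSpec, Thm: float) -> list[ThermoFunctions]:
    """Closed-form solution functions implied by the truth coefficients.

    At composition w the noiseless model is ln x3 = A(w) + M(w)/T with
    A = w a1 + (1-w) a2 and M = w m1 + (1-w) m2, so the mean-centered
    van't Hoff fit recovers slope M and intercept A + M/Thm, giving
    dH = -R M and dG = -R Thm A - R M exactly.
    """
    t = spec.truth
    out = []
    for w in spec.w1_grid:
        A = w * t.a1 + (1.0 - w) * t.a2
        M = w * t.m1 + (1.0 - w) * t.m2
        dH = -R * M / 1000.0
        dG = -R * Thm * (A + M / Thm) / 1000.0
        TdS = dH - dG
        out.append(
            ThermoFunctions(
                w1=w,
                dG=dG,
                dH=dH,
                dS=TdS * 1000.0 / Thm,
                TdS=TdS,
                Thm=Thm,
                process="solution",
            )
        )
    return out
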