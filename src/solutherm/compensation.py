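"""Enthalpy-entropy compensation (EEC) diagnostic.

Following Bustamante's graphical method, the apparent solution enthalpy is
regressed on the apparent solution Gibbs energy across solvent compositions.
A positive slope marks an enthalpy-driven process, a negative slope an
entropy-driven one; near-perfect linearity indicates strong compensation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .vanthoff import ThermoFunctions

__all__ = ["EecResult", "eec_fit"]


@dataclass(frozen=True)
class EecResult:
    """OLS of dH (y) on dG (x) across compositions."""

    slope: float  # dimensionless
    intercept: float  # kJ/mol
    r2: float
    n: int

    @property
    def driver(self) -> str:
        """``"enthalpy"`` for positive slope, ``"entropy"`` otherwise."""
        return "enthalpy" if self.slope > 0 else "entropy"


def eec_fit(
    rows: Sequence[ThermoFunctions] | Sequence[tuple[float, float]],
) -> EecResult:
    """Fit the compensation line through (dG, dH) pairs.

    ``rows`` are ThermoFunctions or plain (dG, dH) tuples; order is
    irrelevant. At least three pairs with spread in dG are required.
    """
    if rows and isinstance(rows[0], ThermoFunctions):
        dG = np.asarray([r.dG for r in rows], dtype=float)  # type: ignore[union-attr]
        dH = np.asarray([r.dH for r in rows], dtype=float)  # type: ignore[union-attr]
    else:
        dG = np.asarray([r[0] for r in rows], dtype=float)
        dH = np.asarray([r[1] for r in rows], dtype=float)
    if len(dG) < 3:
        raise InsufficientDataError("need >= 3 (dG, dH) pairs for EEC")
    if not np.all(np.isfinite(dG)) or not np.all(np.isfinite(dH)):
        raise DomainError("non-finite dG or dH in EEC input")
    if np.ptp(dG) == 0.0:
        raise DomainError("zero variance in dG: compensation fit degenerate")
    res = stats.linregress(dG, dH)
    return EecResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        n=len(dG),
    )
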