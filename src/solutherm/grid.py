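"""Solubility-grid domain types, delimited-text I/O and validation.

A *solubility grid* is a set of equilibrium mole-fraction solubilities x3 of
a solute (component 3) measured over compositions of a binary solvent mixture
(mass fraction ``w1`` of solvent 1; solvent 2 makes up the remainder,
``w2 = 1 - w1``, which is therefore never stored) and over temperature.
Regression over temperature requires a *rectangular* grid: every composition
measured at the same ordered set of temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, GridFormatError, GridValidationError

__all__ = [
    "SolubilityPoint",
    "SolubilityGrid",
    "FusionProperties",
    "GridDialect",
    "GridReport",
    "load_grid",
    "write_grid",
    "validate_grid",
    "harmonic_mean_temperature",
]

#: Absolute tolerance (K) when deciding two stored temperatures are the same
#: level of the grid; generous enough to survive text round-trips.
TEMPERATURE_ATOL = 1e-6


@dataclass(frozen=True)
class SolubilityPoint:
    """One saturated-solution measurement.

    Parameters
    ----------
    w1 : float
        Mass fraction of solvent 1 in the solute-free solvent mixture (0-1).
    T : float
        Absolute temperature in K.
    x3 : float
        Mole-fraction solubility of the solute, strictly inside (0, 1).
    u_x3 : float, optional
        Standard uncertainty of ``x3`` on the same scale.
    """

    w1: float
    T: float
    x3: float
    u_x3: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise GridValidationError(f"w1={self.w1!r} outside [0, 1]")
        if not self.T > 0.0:
            raise GridValidationError(f"T={self.T!r} must be positive (K)")
        if not 0.0 < self.x3 < 1.0:
            raise GridValidationError(
                f"x3={self.x3!r} must lie strictly in (0, 1)"
            )
        if self.u_x3 is not None and self.u_x3 < 0.0:
            raise GridValidationError(f"u_x3={self.u_x3!r} must be >= 0")

    @property
    def w2(self) -> float:
        """Mass fraction of solvent 2 (always computed, never stored)."""
        return 1.0 - self.w1


@dataclass
class SolubilityGrid:
    """A collection of :class:`SolubilityPoint` over (w1, T).

    Points are kept sorted by (w1, T). Duplicate (w1, T) pairs are rejected
    at construction; rectangularity is *reported* by :func:`validate_grid`
    and *enforced* only by operations that regress over temperature.
    """

    points: list[SolubilityPoint]
    labels: tuple[str, str] = ("solvent 1", "solvent 2")

    def __post_init__(self) -> None:
        if not self.points:
            raise GridValidationError("grid needs at least one point")
        self.points = sorted(self.points, key=lambda p: (p.w1, p.T))
        seen: set[tuple[float, float]] = set()
        for p in self.points:
            key = (p.w1, round(p.T / TEMPERATURE_ATOL))
            if key in seen:
                raise GridValidationError(f"duplicate (w1, T) = ({p.w1}, {p.T})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def compositions(self) -> np.ndarray:
        """Sorted distinct ``w1`` values."""
        return np.unique([p.w1 for p in self.points])

    @property
    def temperatures(self) -> np.ndarray:
        """Sorted distinct temperatures (K), merged at ``TEMPERATURE_ATOL``."""
        ts = sorted({round(p.T / TEMPERATURE_ATOL) for p in self.points})
        return np.asarray([t * TEMPERATURE_ATOL for t in ts])

    def column(self, w1: float) -> list[SolubilityPoint]:
        """All points at one composition, ordered by temperature."""
        col = [p for p in self.points if p.w1 == w1]
        if not col:
            raise KeyError(f"no points at w1={w1}")
        return col

    def is_rectangular(self) -> bool:
        nT = len(self.temperatures)
        return all(len(self.column(w)) == nT for w in self.compositions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w1": [p.w1 for p in self.points],
                "T_K": [p.T for p in self.points],
                "x3": [p.x3 for p in self.points],
                "u_x3": [p.u_x3 for p in self.points],
            }
        )


@dataclass(frozen=True)
class FusionProperties:
    """Fusion (melting) properties of the solute.

    ``dCp_mode`` selects the heat-capacity convention of the ideal-solubility
    model:

    - ``"fusion-entropy"`` (default): dCp approximated by the fusion entropy
      dH_fus/Tm, the usual Hildebrand-style correction;
    - ``"explicit"``: a measured ``dCp`` (J mol^-1 K^-1) is supplied;
    - ``"zero"``: no heat-capacity correction (plain van't Hoff fusion form).
    """

    dH_fus: float  # kJ mol^-1
    Tm: float  # K
    dCp_mode: str = "fusion-entropy"
    dCp: float | None = None  # J mol^-1 K^-1, only for mode "explicit"

    def __post_init__(self) -> None:
        if self.dH_fus <= 0:
            raise GridValidationError("dH_fus must be positive (kJ/mol)")
        if self.Tm <= 0:
            raise GridValidationError("Tm must be positive (K)")
        if self.dCp_mode not in ("fusion-entropy", "explicit", "zero"):
            raise GridValidationError(f"unknown dCp_mode {self.dCp_mode!r}")
        if self.dCp_mode == "explicit":
            if self.dCp is None:
                raise GridValidationError("dCp required when dCp_mode='explicit'")
            if self.dCp < 0:
                raise GridValidationError("dCp must be >= 0")

    @property
    def dCp_effective(self) -> float:
        """Heat-capacity change actually used, J mol^-1 K^-1."""
        if self.dCp_mode == "zero":
            return 0.0
        if self.dCp_mode == "explicit":
            return float(self.dCp)  # type: ignore[arg-type]
        return self.dH_fus * 1000.0 / self.Tm


@dataclass(frozen=True)
class GridDialect:
    """How a delimited-text solubility file maps onto a grid.

    ``x3_scale`` multiplies the stored column to recover the true mole
    fraction — tables are often printed as 10^4 x3, and the scale must be
    explicit to avoid silent four-orders-of-magnitude errors.
    """

    w1_col: str = "w1"
    T_col: str = "T_K"
    x3_col: str = "x3"
    u_x3_col: str | None = "u_x3"
    sep: str = ","
    x3_scale: float = 1.0


@dataclass
class GridReport:
    """Validation findings for a grid; empty iff regression-ready."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.issues)


def harmonic_mean_temperature(temps: Iterable[float]) -> float:
    """Harmonic mean n / sum(1/Ti) of a set of temperatures.

    This is the reference temperature at which mean-centered van't Hoff
    regression reports its thermodynamic functions: centring the regressor
    1/T at 1/Thm makes the intercept the mean of ln x3 and decorrelates
    slope and intercept estimates.
    """
    ts = np.asarray(list(temps), dtype=float)
    if ts.size == 0:
        raise DomainError("need at least one temperature")
    if np.any(ts <= 0):
        raise DomainError("temperatures must be positive (K)")
    return float(ts.size / np.sum(1.0 / ts))


def load_grid(
    path: str | Path,
    dialect: GridDialect | None = None,
    labels: tuple[str, str] = ("solvent 1", "solvent 2"),
) -> SolubilityGrid:
    """Read a delimited-text solubility table into a validated grid.

    Raises
    ------
    GridFormatError
        Missing column or non-numeric cell (reported with its row index).
    GridValidationError
        Out-of-range values or duplicate (w1, T) pairs.
    """
    dialect = dialect or GridDialect()
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=dialect.sep)
    needed = [dialect.w1_col, dialect.T_col, dialect.x3_col]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise GridFormatError(f"missing column(s) {missing} in {path}")
    use_u = dialect.u_x3_col is not None and dialect.u_x3_col in df.columns
    cols = needed + ([dialect.u_x3_col] if use_u else [])
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise GridFormatError(
                f"non-numeric value in column {col!r} at row {int(bad[0])}"
            )
        df[col] = coerced
    points = []
    for idx, row in df.iterrows():
        u = row[dialect.u_x3_col] if use_u else None
        if u is not None and (isinstance(u, float) and math.isnan(u)):
            u = None
        try:
            points.append(
                SolubilityPoint(
                    w1=float(row[dialect.w1_col]),
                    T=float(row[dialect.T_col]),
                    x3=float(row[dialect.x3_col]) * dialect.x3_scale,
                    u_x3=None if u is None else float(u) * dialect.x3_scale,
                )
            )
        except GridValidationError as err:
            raise GridValidationError(f"row {int(idx)}: {err}") from err
    return SolubilityGrid(points=points, labels=labels)


def write_grid(
    grid: SolubilityGrid, path: str | Path, dialect: GridDialect | None = None
) -> None:
    """Write a grid back to delimited text (inverse of :func:`load_grid`)."""
    dialect = dialect or GridDialect()
    df = grid.to_frame()
    out = pd.DataFrame(
        {
            dialect.w1_col: df["w1"],
            dialect.T_col: df["T_K"],
            dialect.x3_col: df["x3"] / dialect.x3_scale,
        }
    )
    if dialect.u_x3_col is not None:
        out[dialect.u_x3_col] = df["u_x3"] / dialect.x3_scale
    out.to_csv(path, sep=dialect.sep, index=False)


def validate_grid(
    grid: SolubilityGrid, temps: Sequence[float] | None = None
) -> GridReport:
    """Report invariant violations that matter for temperature regression.

    Construction already guarantees per-point ranges and no duplicates, so the
    report concentrates on grid shape: every composition must carry the same
    ordered temperature set (rectangularity).
    """
    report = GridReport()
    all_temps = grid.temperatures if temps is None else np.asarray(temps, float)
    for w in grid.compositions:
        col_t = np.asarray([p.T for p in grid.column(w)])
        if len(col_t) != len(all_temps) or not np.allclose(
            col_t, all_temps, atol=TEMPERATURE_ATOL, rtol=0.0
        ):
            missing = [
                f"{t:.2f}"
                for t in all_temps
                if not np.any(np.isclose(col_t, t, atol=TEMPERATURE_ATOL, rtol=0.0))
            ]
            report.issues.append(
                f"w1={w}: temperature set differs from grid "
                f"(missing: {', '.join(missing) or 'none; extra levels present'})"
            )
    return report
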