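"""End-to-end analysis runs and report bundles.

`run_analyze` drives the full pipeline on one grid — harmonic mean
temperature, per-composition van't Hoff fits, solution and mixing
thermodynamic tables, the enthalpy-entropy compensation line, and the
four-parameter cosolvency model with its validation statistics — and writes
every table plus a run log recording the constants and conventions in force.
CSV outputs keep full precision; the printed summary rounds to the
conventional reporting precision (2 decimals for kJ/mol, 1 for J/mol/K,
3 for zeta).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compensation import EecResult, eec_fit
from .constants import R
from .cosolvency import ValidationReport, VhYrModel, build_model, predict, validate
from .exceptions import SoluthermError
from .grid import FusionProperties, GridDialect, SolubilityGrid, load_grid, validate_grid
from .ideal import ideal_thermodynamics, mixing_table
from .vanthoff import SolutionAnalysis, analyze_grid

__all__ = ["RunConfig", "AnalysisBundle", "run_analyze", "run_predict"]


@dataclass
class RunConfig:
    """Configuration of one analysis run; every field maps to a CLI flag."""

    input: str | Path | None = None
    dialect: GridDialect = field(default_factory=GridDialect)
    fusion: FusionProperties = field(
        default_factory=lambda: FusionProperties(dH_fus=41.3, Tm=508.5)
    )
    fit_mode: str = "two-point"  # or "all-temps"
    mrd_reference: str = "experimental"  # or "calculated"
    outdir: str | Path | None = None
    plots: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key=value JSON config; keyword overrides win."""
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        fusion = FusionProperties(
            dH_fus=raw.pop("fusion_dh", 41.3),
            Tm=raw.pop("fusion_tm", 508.5),
            dCp_mode=raw.pop("dcp_mode", "fusion-entropy"),
            dCp=raw.pop("dcp", None),
        )
        dialect = GridDialect(
            w1_col=raw.pop("w1_col", "w1"),
            T_col=raw.pop("T_col", "T_K"),
            x3_col=raw.pop("x3_col", "x3"),
            u_x3_col=raw.pop("u_x3_col", "u_x3"),
            sep=raw.pop("sep", ","),
            x3_scale=raw.pop("x3_scale", 1.0),
        )
        known = {k: raw[k] for k in ("input", "fit_mode", "mrd_reference", "outdir", "plots") if k in raw}
        return cls(dialect=dialect, fusion=fusion, **known)


@dataclass
class AnalysisBundle:
    """Everything one analysis run computes."""

    grid: SolubilityGrid
    analysis: SolutionAnalysis
    mixing: pd.DataFrame
    eec: EecResult
    model: VhYrModel
    validation: ValidationReport
    config: RunConfig

    def summary(self) -> str:
        a = self.analysis
        lines = [
            f"solutherm {__version__} analysis",
            f"points: {len(self.grid)}  compositions: {len(a.thermo)}  "
            f"temperatures: {len(self.grid.temperatures)}",
            f"harmonic mean temperature Thm = {a.Thm:.1f} K  (R = {R} J/mol/K)",
            "",
            "solution thermodynamics at Thm (kJ/mol; dS in J/mol/K):",
        ]
        df = a.to_frame()
        show = pd.DataFrame(
            {
                "w1": df.w1,
                "dG": df.dG_kJ_mol.round(2),
                "dH": df.dH_kJ_mol.round(2),
                "dS": df.dS_J_mol_K.round(1),
                "TdS": df.TdS_kJ_mol.round(2),
                "zeta_H": df.zeta_H.round(3),
                "zeta_TS": df.zeta_TS.round(3),
            }
        )
        lines.append(show.to_string(index=False))
        mix = self.mixing
        lines += [
            "",
            "mixing functions at Thm (solution minus ideal; "
            f"dH_fus={self.config.fusion.dH_fus} kJ/mol, Tm={self.config.fusion.Tm} K, "
            f"dCp mode={self.config.fusion.dCp_mode}):",
            pd.DataFrame(
                {
                    "w1": mix.w1,
                    "dG_mix": mix.dG_mix_kJ_mol.round(2),
                    "dH_mix": mix.dH_mix_kJ_mol.round(2),
                    "dS_mix": mix.dS_mix_J_mol_K.round(1),
                }
            ).to_string(index=False),
            "",
            f"enthalpy-entropy compensation: slope={self.eec.slope:.3f} "
            f"intercept={self.eec.intercept:.2f} kJ/mol r2={self.eec.r2:.3f} "
            f"-> {self.eec.driver}-driven",
            "",
            f"cosolvency model ({self.config.fit_mode}): "
            f"ln x = w1({self.model.a1:.3f} {self.model.m1:+.1f}/T) "
            f"+ w2({self.model.a2:.3f} {self.model.m2:+.1f}/T)",
            f"validation over {self.validation.n} points "
            f"({self.validation.reference} reference): "
            f"MRD = {self.validation.mrd:.2f}%  "
            f"signed {self.validation.mrd_signed:+.2f}%  "
            f"r2 = {self.validation.r2:.3f}",
        ]
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.analysis.to_frame().to_csv(out / "solution_thermo.csv", index=False)
        self.mixing.to_csv(out / "mixing_thermo.csv", index=False)
        results = {
            "Thm_K": self.analysis.Thm,
            "R_J_mol_K": R,
            "eec": {
                "slope": self.eec.slope,
                "intercept_kJ_mol": self.eec.intercept,
                "r2": self.eec.r2,
                "driver": self.eec.driver,
            },
            "model": {
                "a1": self.model.a1,
                "m1": self.model.m1,
                "a2": self.model.a2,
                "m2": self.model.m2,
                "fit_mode": self.config.fit_mode,
            },
            "validation": {
                "mrd_percent": self.validation.mrd,
                "mrd_signed_percent": self.validation.mrd_signed,
                "r2": self.validation.r2,
                "n": self.validation.n,
                "reference": self.validation.reference,
            },
        }
        (out / "results.json").write_text(json.dumps(results, indent=2))
        (out / "run_log.txt").write_text(self.summary() + "\n" + self._decisions())
        if self.config.plots:
            self._write_plots(out)

    def _decisions(self) -> str:
        c = self.config
        return (
            "\nconventions in force:\n"
            f"  dCp mode: {c.fusion.dCp_mode} "
            f"(effective dCp = {c.fusion.dCp_effective:.2f} J/mol/K)\n"
            f"  model fit mode: {c.fit_mode}\n"
            f"  MRD reference denominator: {c.mrd_reference} (absolute convention; "
            "signed mean also reported)\n"
            "  van't Hoff regression: unweighted OLS of ln x3 on (1/T - 1/Thm)\n"
        )

    def _write_plots(self, out: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        # van't Hoff lines
        fig, ax = plt.subplots(figsize=(6, 4.5))
        import numpy as np

        for w in self.grid.compositions:
            col = self.grid.column(w)
            ax.plot(
                [1e3 / p.T for p in col],
                [np.log(p.x3) for p in col],
                "o-",
                ms=3,
                lw=0.8,
                label=f"w1={w:g}",
            )
        ax.set_xlabel("1000/T (1/K)")
        ax.set_ylabel("ln x3")
        fig.savefig(out / "vant_hoff.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        # EEC
        fig, ax = plt.subplots(figsize=(5, 4))
        dG = [t.dG for t in self.analysis.thermo]
        dH = [t.dH for t in self.analysis.thermo]
        ax.plot(dG, dH, "ko", ms=4)
        xs = np.linspace(min(dG), max(dG), 10)
        ax.plot(xs, self.eec.intercept + self.eec.slope * xs, "r-", lw=1)
        ax.set_xlabel("dG_soln (kJ/mol)")
        ax.set_ylabel("dH_soln (kJ/mol)")
        fig.savefig(out / "eec.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        # parity
        fig, ax = plt.subplots(figsize=(5, 4))
        xE = [p.x3 for p in self.grid.points]
        xC = predict(
            self.model,
            [p.w1 for p in self.grid.points],
            [p.T for p in self.grid.points],
        )
        ax.plot(xE, xC, "b.", ms=3)
        lim = [0, max(max(xE), max(xC)) * 1.05]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("experimental x3")
        ax.set_ylabel("predicted x3")
        fig.savefig(out / "parity.png", dpi=150, bbox_inches="tight")
        plt.close(fig)


def run_analyze(config: RunConfig, grid: SolubilityGrid | None = None) -> AnalysisBundle:
    """Run the full pipeline; loads the grid from config.input unless given."""
    if grid is None:
        if config.input is None:
            raise SoluthermError("no input grid configured")
        grid = load_grid(config.input, config.dialect)
    report = validate_grid(grid)
    if not report.ok:
        raise SoluthermError(f"grid not regression-ready:\n{report}")
    analysis = analyze_grid(grid)
    ideal = ideal_thermodynamics(config.fusion, analysis.Thm)
    mixing = mixing_table(analysis, config.fusion)
    eec = eec_fit(analysis.thermo)
    model = build_model(grid, fit=config.fit_mode)
    validation = validate(model, grid, reference=config.mrd_reference)
    bundle = AnalysisBundle(
        grid=grid,
        analysis=analysis,
        mixing=mixing,
        eec=eec,
        model=model,
        validation=validation,
        config=config,
    )
    # ideal row is implicit in mixing; keep it reachable for callers
    bundle.ideal = ideal  # type: ignore[attr-defined]
    if config.outdir is not None:
        bundle.write(config.outdir)
    return bundle


def run_predict(
    model: VhYrModel, points: pd.DataFrame, grid: SolubilityGrid | None = None
) -> pd.DataFrame:
    """Predict x3 at the (w1, T_K) rows of ``points``; if a grid is supplied,
    attach experimental values and relative deviations where they exist."""
    out = points.copy()
    if len(out):
        out["x3_pred"] = predict(model, out["w1"].values, out["T_K"].values)
    else:
        out["x3_pred"] = pd.Series(dtype=float)
    if grid is not None and len(out):
        lookup = {(p.w1, p.T): p.x3 for p in grid.points}
        out["x3_exp"] = [lookup.get((w, t)) for w, t in zip(out.w1, out.T_K)]
        out["rel_dev_percent"] = 100.0 * (out.x3_exp - out.x3_pred) / out.x3_exp
    return out
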