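"""Mean-centered van't Hoff regression and solution thermodynamics."""

import numpy as np
import pytest

import solutherm as st
from solutherm.constants import R
from solutherm.exceptions import (
    DomainError,
    GridValidationError,
    InsufficientDataError,
)

TEMPS = [278.15 + 5 * i for i in range(9)]
THM = st.harmonic_mean_temperature(TEMPS)


def closed_form_ols(x, y):
    """Independent oracle: two-variable least squares via normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    slope = (n * np.sum(x * y) - x.sum() * y.sum()) / (
        n * np.sum(x * x) - x.sum() ** 2
    )
    intercept = (y.sum() - slope * x.sum()) / n
    return slope, intercept


def synthetic_column(a, m, temps=TEMPS, thm=THM):
    return [(T, np.exp(a + m * (1 / T - 1 / thm))) for T in temps]


class TestFit:
    def test_recovers_exact_line(self):
        fit = st.fit_vant_hoff(synthetic_column(-8.0, -3600.0), THM)
        assert fit.a == pytest.approx(-8.0, abs=1e-12)
        assert fit.m == pytest.approx(-3600.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.se_m == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_normal_equations(self, paper_grid, analysis):
        for w in (0.0, 0.5, 1.0):
            col = paper_grid.column(w)
            x = [1 / p.T - 1 / analysis.Thm for p in col]
            y = [np.log(p.x3) for p in col]
            slope, intercept = closed_form_ols(x, y)
            fit = st.fit_vant_hoff(col, analysis.Thm)
            assert fit.m == pytest.approx(slope, rel=1e-10)
            assert fit.a == pytest.approx(intercept, rel=1e-10)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            st.fit_vant_hoff(synthetic_column(-8, -3600, temps=TEMPS[:2]), THM)

    def test_duplicate_temperature_rejected(self):
        pts = synthetic_column(-8, -3600, temps=[278.15, 278.15, 318.15])
        with pytest.raises(GridValidationError):
            st.fit_vant_hoff(pts, THM)

    def test_mixed_compositions_rejected(self, paper_grid):
        pts = paper_grid.column(0.0)[:5] + paper_grid.column(1.0)[:5]
        with pytest.raises(GridValidationError):
            st.fit_vant_hoff(pts, THM)

    def test_nonpositive_solubility_rejected(self):
        with pytest.raises(DomainError):
            st.fit_vant_hoff([(278.15, 1e-4), (288.15, -1e-4), (298.15, 1e-4)], THM)


class TestSolutionThermo:
    def test_null_process(self):
        fit = st.VantHoffFit(
            w1=0.0, m=0.0, a=0.0, se_m=0.0, se_a=0.0, r2=1.0, n=9, Thm=THM
        )
        t = st.solution_thermodynamics(fit)
        assert t.dH == 0.0 and t.dG == 0.0 and t.dS == 0.0
        assert t.zeta_H is None  # partition undefined for a null process

    def test_identity_dG_eq_dH_minus_TdS(self, analysis):
        for t in analysis.thermo:
            assert t.dG == pytest.approx(t.dH - t.TdS, abs=1e-9)
            assert t.dS == pytest.approx(t.TdS * 1000 / analysis.Thm, abs=1e-9)

    def test_uncertainty_propagation(self):
        fit = st.VantHoffFit(
            w1=0.0, m=-3600.0, a=-8.0, se_m=25.0, se_a=0.01, r2=0.999, n=9,
            Thm=THM,
        )
        t = st.solution_thermodynamics(fit)
        assert t.u_dH == pytest.approx(R * 25.0 / 1000)
        assert t.u_dG == pytest.approx(R * THM * 0.01 / 1000)
        assert t.u_dS == pytest.approx(
            np.hypot(t.u_dH, t.u_dG) * 1000 / THM
        )


class TestZetaPartition:
    @pytest.mark.parametrize(
        "dH,TdS,expected", [(31.15, 11.32, 0.733), (0.0, 5.0, 0.0), (5.0, 0.0, 1.0)]
    )
    def test_values(self, dH, TdS, expected):
        zh, zts = st.zeta_partition(dH, TdS)
        assert zh == pytest.approx(expected, abs=5e-4)
        assert zh + zts == pytest.approx(1.0, abs=1e-15)

    def test_undefined_partition(self):
        with pytest.raises(DomainError):
            st.zeta_partition(0.0, 0.0)


class TestAnalyzeGrid:
    def test_noiseless_grid_recovered_everywhere(self):
        spec = st.SyntheticSpec(noise_cv=0.0)
        grid = st.generate_grid(spec)
        analysis = st.analyze_grid(grid)
        truth = st.ground_truth_thermo(spec, analysis.Thm)
        for est, true in zip(analysis.thermo, truth):
            assert est.dH == pytest.approx(true.dH, abs=1e-9)
            assert est.dG == pytest.approx(true.dG, abs=1e-9)

    def test_three_temperature_subgrid_matches_oracle(self, paper_grid):
        keep = {278.15, 298.15, 318.15}
        pts = [p for p in paper_grid.points if p.T in keep]
        sub = st.SolubilityGrid(points=pts)
        analysis = st.analyze_grid(sub)
        thm3 = st.harmonic_mean_temperature(sorted(keep))
        assert analysis.Thm == pytest.approx(thm3)
        col = sub.column(0.0)
        slope, intercept = closed_form_ols(
            [1 / p.T - 1 / thm3 for p in col], [np.log(p.x3) for p in col]
        )
        assert analysis.thermo[0].dH == pytest.approx(-R * slope / 1000, rel=1e-10)
        assert analysis.thermo[0].dG == pytest.approx(
            -R * thm3 * intercept / 1000, rel=1e-10
        )

    def test_nonrectangular_rejected(self, paper_grid):
        pts = [
            p
            for p in paper_grid.points
            if not (p.w1 == 0.5 and abs(p.T - 298.15) < 1e-9)
        ]
        with pytest.raises(GridValidationError):
            st.analyze_grid(st.SolubilityGrid(points=pts))

    def test_dH_within_three_se_of_truth(self):
        """Propagated standard errors are calibrated: with nine-point fits
        the estimated SE carries 7 residual degrees of freedom, so the
        +-3 SE interval covers truth with probability P(|t_7| <= 3) ~ 98%;
        observed coverage over seeded replicates must sit near that."""
        n_rep, hits, total = 300, 0, 0
        w1s = [0.0, 0.5, 1.0]
        for seed in range(n_rep):
            spec = st.SyntheticSpec(noise_cv=0.02, seed=seed, w1_grid=w1s)
            grid = st.generate_grid(spec)
            analysis = st.analyze_grid(grid)
            truth = st.ground_truth_thermo(spec, analysis.Thm)
            for est, true in zip(analysis.thermo, truth):
                total += 1
                if abs(est.dH - true.dH) <= 3 * est.u_dH:
                    hits += 1
        coverage = hits / total
        assert 0.965 <= coverage  # t_7 theory: 0.980; binomial sd ~ 0.005
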