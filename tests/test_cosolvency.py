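"""Four-parameter hybrid cosolvency model and its validation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import solutherm as st
from solutherm.cosolvency import deviation_summary
from solutherm.exceptions import DomainError, InsufficientDataError

from conftest import EQ13

MODEL = st.VhYrModel(**EQ13)


class TestTwoPoint:
    def test_published_coefficients(self, paper_grid):
        """Endpoint cells of each pure-solvent column reproduce the published
        four coefficients to within the table's rounding (~0.3%)."""
        mecn = paper_grid.column(1.0)
        a1, m1 = st.fit_two_point(mecn[0].x3, mecn[-1].x3, mecn[0].T, mecn[-1].T)
        etoh = paper_grid.column(0.0)
        a2, m2 = st.fit_two_point(etoh[0].x3, etoh[-1].x3, etoh[0].T, etoh[-1].T)
        assert a1 == pytest.approx(EQ13["a1"], rel=3e-3)
        assert m1 == pytest.approx(EQ13["m1"], rel=3e-3)
        assert a2 == pytest.approx(EQ13["a2"], rel=3e-3)
        assert m2 == pytest.approx(EQ13["m2"], rel=3e-3)

    def test_flat_solubility(self):
        a, m = st.fit_two_point(2e-4, 2e-4, 278.15, 318.15)
        assert m == 0.0
        assert a == pytest.approx(math.log(2e-4))

    def test_equal_temperatures_degenerate(self):
        with pytest.raises(DomainError):
            st.fit_two_point(1e-4, 2e-4, 298.15, 298.15)

    def test_nonpositive_solubility(self):
        with pytest.raises(DomainError):
            st.fit_two_point(0.0, 2e-4, 278.15, 318.15)


class TestBuildModel:
    def test_exact_recovery_from_synthetic(self):
        grid = st.generate_grid(st.SyntheticSpec(noise_cv=0.0))
        model = st.build_model(grid)
        for name in ("a1", "m1", "a2", "m2"):
            assert getattr(model, name) == pytest.approx(
                getattr(st.synthetic.DEFAULT_TRUTH, name), rel=1e-10
            )

    def test_all_temps_mode_exact_on_noiseless(self):
        grid = st.generate_grid(st.SyntheticSpec(noise_cv=0.0))
        model = st.build_model(grid, fit="all-temps")
        for name in ("a1", "m1", "a2", "m2"):
            assert getattr(model, name) == pytest.approx(
                getattr(st.synthetic.DEFAULT_TRUTH, name), rel=1e-9
            )

    def test_missing_pure_column(self, paper_grid):
        pts = [p for p in paper_grid.points if p.w1 != 1.0]
        with pytest.raises(InsufficientDataError):
            st.build_model(st.SolubilityGrid(points=pts))

    def test_unknown_mode(self, paper_grid):
        with pytest.raises(ValueError):
            st.build_model(paper_grid, fit="bogus")


class TestPredict:
    def test_hand_evaluated_point(self):
        # pure solvent 1 at the cold end of the published model
        x = st.predict(MODEL, 1.0, 278.15)
        assert x == pytest.approx(math.exp(5.086 - 3260.9 / 278.15), rel=1e-12)
        assert x == pytest.approx(1.311e-3, rel=1e-3)
        assert x == pytest.approx(13.09e-4, rel=0.01)  # measured cell

    def test_endpoint_reduces_to_pure_line(self):
        T = 300.0
        assert st.predict(MODEL, 0.0, T) == pytest.approx(
            math.exp(MODEL.a2 + MODEL.m2 / T), rel=1e-14
        )

    def test_midpoint_is_geometric_mean(self):
        T = 305.0
        gm = math.sqrt(st.predict(MODEL, 0.0, T) * st.predict(MODEL, 1.0, T))
        assert st.predict(MODEL, 0.5, T) == pytest.approx(gm, rel=1e-12)

    @settings(deadline=None)
    @given(
        w=hst.floats(min_value=0.0, max_value=1.0),
        T=hst.floats(min_value=250.0, max_value=350.0),
    )
    def test_log_linearity_in_composition(self, w, T):
        lhs = math.log(st.predict(MODEL, w, T))
        rhs = w * math.log(st.predict(MODEL, 1.0, T)) + (1 - w) * math.log(
            st.predict(MODEL, 0.0, T)
        )
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_monotone_in_temperature_for_negative_slopes(self):
        T = np.linspace(260, 340, 50)
        x = st.predict(MODEL, 0.3, T)
        assert np.all(np.diff(x) > 0)

    def test_extrapolation_flagged(self):
        with pytest.raises(DomainError):
            st.predict(MODEL, 1.2, 300.0)
        assert st.predict(MODEL, 1.2, 300.0, extrapolate=True) > 0


class TestValidate:
    def test_exact_interpolation(self):
        grid = st.generate_grid(st.SyntheticSpec(noise_cv=0.0))
        rep = st.validate(st.synthetic.DEFAULT_TRUTH, grid)
        assert rep.mrd == pytest.approx(0.0, abs=1e-10)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)
        assert rep.n == len(grid)

    def test_toy_mean_relative_deviation(self):
        # hand-computed: deviations 10%, 10%, 0% -> mean 20/3 %
        rep = deviation_summary(
            [1e-4, 2e-4, 4e-4], [1.1e-4, 1.8e-4, 4e-4]
        )
        assert rep.mrd == pytest.approx(20.0 / 3.0, rel=1e-12)
        assert rep.mrd_signed == pytest.approx(0.0, abs=1e-10)
        assert list(np.round(rep.residuals, 6)) == [-10.0, 10.0, 0.0]

    def test_reference_denominator(self):
        repE = deviation_summary([1e-4], [2e-4], reference="experimental")
        repC = deviation_summary([1e-4], [2e-4], reference="calculated")
        assert repE.mrd == pytest.approx(100.0)
        assert repC.mrd == pytest.approx(50.0)
        with pytest.raises(ValueError):
            deviation_summary([1e-4], [2e-4], reference="bogus")

    def test_published_model_against_full_grid(self, paper_grid):
        rep = st.validate(MODEL, paper_grid)
        assert rep.n == 189
        assert rep.r2 > 0.98
        # experimental-reference absolute convention: ~6.9% for this model
        assert 5.0 < rep.mrd < 8.0
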