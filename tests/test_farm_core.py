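"""Unit-farm nitrogen budget: closed forms, feedback, fixed point, sweep."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nsafarm import (
    ConvergenceError,
    CyclingCoefficients,
    DivergentFeedbackError,
    FarmGeometry,
    NitrogenInputs,
    ParameterError,
    RetentionCurve,
    gamma_sweep,
    solve_closed_form,
    solve_fixed_point,
    solve_general_gamma,
)
from nsafarm.farm_core import eq_single_expression_yield_vegetal

GEOM = FarmGeometry(area_vegetal=1.0, area_forage=0.43, gamma=1.0)
INPUTS = NitrogenInputs(deposition=10.0, fixation_vegetal=20.0, fixation_forage=100.0)
COEFF = CyclingCoefficients(alpha=50.0, beta=0.002)


class TestClosedForm:
    def test_reference_solution(self):
        """Hand-substituted sequential solution: y_f, then herd, then y_v."""
        sol = solve_closed_form(GEOM, INPUTS, COEFF, rho_v=0.5, rho_f=0.6)
        assert sol.yield_forage == pytest.approx(66.0, rel=1e-12)
        assert sol.n_mother_cows == pytest.approx(0.05676, rel=1e-12)
        assert sol.yield_vegetal == pytest.approx(16.419, rel=1e-12)

    def test_zero_inputs_give_zero_solution(self):
        zero = NitrogenInputs(0.0, 0.0, 0.0)
        sol = solve_closed_form(GEOM, zero, COEFF, 0.5, 0.6)
        assert sol.yield_vegetal == sol.yield_forage == sol.n_mother_cows == 0.0

    def test_alpha_zero_severs_manure_link(self):
        coeff = CyclingCoefficients(alpha=0.0, beta=0.002)
        sol = solve_closed_form(GEOM, INPUTS, coeff, rho_v=0.5, rho_f=0.6)
        assert sol.yield_vegetal == pytest.approx(0.5 * 30.0, rel=1e-14)

    def test_rejects_non_unit_gamma(self):
        geom = FarmGeometry(1.0, 0.43, gamma=0.5)
        with pytest.raises(ParameterError, match="gamma"):
            solve_closed_form(geom, INPUTS, COEFF, 0.5, 0.6)

    @pytest.mark.parametrize("rho", [0.0, -0.1, 1.2])
    def test_rejects_rho_outside_unit_interval(self, rho):
        with pytest.raises(ParameterError):
            solve_closed_form(GEOM, INPUTS, COEFF, rho, 0.6)

    def test_matches_single_expression_form(self):
        """The combined one-line expression (with rho_v on both terms)
        equals the sequential solve to machine precision."""
        sol = solve_closed_form(GEOM, INPUTS, COEFF, 0.5, 0.6)
        direct = eq_single_expression_yield_vegetal(GEOM, INPUTS, COEFF, 0.5, 0.6)
        assert sol.yield_vegetal == pytest.approx(direct, rel=1e-15)


class TestGeneralGamma:
    def test_gamma_one_reduces_to_closed_form(self):
        a = solve_closed_form(GEOM, INPUTS, COEFF, 0.5, 0.6)
        b = solve_general_gamma(GEOM, INPUTS, COEFF, 0.5, 0.6)
        for attr in ("yield_vegetal", "yield_forage", "n_mother_cows",
                     "leached_vegetal", "leached_forage"):
            x, y = getattr(a, attr), getattr(b, attr)
            assert x == pytest.approx(y, rel=1e-12, abs=1e-15)

    def test_gamma_zero_feedback_solution(self):
        """gamma=0 routes all manure to the forage side: the closed-form
        feedback gives n_m = n_m(gamma=1)/(1 - beta*rho_f*alpha)."""
        geom = FarmGeometry(1.0, 0.43, gamma=0.0)
        sol = solve_general_gamma(geom, INPUTS, COEFF, 0.5, 0.6)
        assert sol.n_mother_cows == pytest.approx(0.05676 / (1 - 0.06), rel=1e-9)
        assert sol.yield_vegetal == pytest.approx(15.0, rel=1e-12)

    def test_gamma_zero_matches_fixed_point_iteration_oracle(self):
        """200-step Picard iteration of the forage/herd pair converges to
        the same herd size as the closed-form feedback algebra."""
        geom = FarmGeometry(1.0, 0.43, gamma=0.0)
        rho_f = 0.6
        n_m = 0.0
        for _ in range(200):
            y_f = rho_f * (10.0 + 100.0 + 1.0 * COEFF.alpha * n_m / 0.43)
            n_m = COEFF.beta * 0.43 * y_f
        sol = solve_general_gamma(geom, INPUTS, COEFF, 0.5, rho_f)
        assert sol.n_mother_cows == pytest.approx(n_m, rel=1e-12)

    def test_supercritical_loop_raises(self):
        geom = FarmGeometry(1.0, 0.43, gamma=0.0)
        coeff = CyclingCoefficients(alpha=1000.0, beta=0.002)
        with pytest.raises(DivergentFeedbackError, match="1.2"):
            solve_general_gamma(geom, INPUTS, coeff, 0.5, 0.6)

    def test_no_forage_land_means_no_herd(self):
        geom = FarmGeometry(1.43, 0.0, gamma=1.0)
        sol = solve_general_gamma(geom, INPUTS, COEFF, 0.5, 0.6)
        assert sol.n_mother_cows == 0.0
        assert sol.yield_forage == 0.0


@st.composite
def budget_instances(draw):
    geom = FarmGeometry(
        area_vegetal=draw(st.floats(0.2, 5.0)),
        area_forage=draw(st.floats(0.0, 5.0)),
        gamma=draw(st.floats(0.0, 1.0)),
    )
    inputs = NitrogenInputs(
        draw(st.floats(0.0, 50.0)),
        draw(st.floats(0.0, 200.0)),
        draw(st.floats(0.0, 300.0)),
    )
    rho_v = draw(st.floats(0.05, 1.0))
    rho_f = draw(st.floats(0.05, 1.0))
    alpha = draw(st.floats(0.0, 200.0))
    # keep the loop subcritical for any gamma in [0, 1]
    beta_max = 0.9 / (rho_f * alpha) if rho_f * alpha > 0 else 0.01
    beta = draw(st.floats(0.0, min(beta_max, 0.01)))
    return geom, inputs, CyclingCoefficients(alpha, beta), rho_v, rho_f


class TestInvariants:
    @given(budget_instances())
    def test_nitrogen_conservation_every_solve_path(self, instance):
        """Per subunit: deposition + fixation + manure = yield + leached."""
        geom, inputs, coeff, rho_v, rho_f = instance
        sol = solve_general_gamma(geom, inputs, coeff, rho_v, rho_f)
        assert sol.conservation_residual() <= 1e-12
        fp = solve_fixed_point(
            geom, inputs, coeff,
            RetentionCurve.constant(rho_v), RetentionCurve.constant(rho_f),
        )
        assert fp.conservation_residual() <= 1e-12

    @given(budget_instances())
    def test_single_expression_equivalence_at_gamma_one(self, instance):
        geom, inputs, coeff, rho_v, rho_f = instance
        geom = FarmGeometry(geom.area_vegetal, max(geom.area_forage, 0.1), 1.0)
        sol = solve_closed_form(geom, inputs, coeff, rho_v, rho_f)
        direct = eq_single_expression_yield_vegetal(geom, inputs, coeff, rho_v, rho_f)
        assert sol.yield_vegetal == pytest.approx(direct, rel=1e-13, abs=1e-13)

    @given(budget_instances())
    def test_human_food_yield_nondecreasing_in_gamma(self, instance):
        """All manure to the vegetal subunit (gamma = 1) maximizes the
        human-food N yield whenever alpha > 0."""
        geom, inputs, coeff, rho_v, rho_f = instance
        if geom.area_forage == 0:
            geom = FarmGeometry(geom.area_vegetal, 0.5, geom.gamma)
        table = gamma_sweep(geom, inputs, coeff, rho_v, rho_f, n_points=11)
        diffs = np.diff(table["yield_vegetal"].to_numpy())
        assert (diffs >= -1e-10 * max(table["yield_vegetal"].max(), 1.0)).all()

    @given(budget_instances(), st.floats(0.1, 7.0))
    def test_yields_homogeneous_degree_one_in_inputs(self, instance, k):
        geom, inputs, coeff, rho_v, rho_f = instance
        scaled = NitrogenInputs(
            k * inputs.deposition,
            k * inputs.fixation_vegetal,
            k * inputs.fixation_forage,
        )
        a = solve_general_gamma(geom, inputs, coeff, rho_v, rho_f)
        b = solve_general_gamma(geom, scaled, coeff, rho_v, rho_f)
        assert b.yield_vegetal == pytest.approx(k * a.yield_vegetal, rel=1e-9, abs=1e-12)
        assert b.yield_forage == pytest.approx(k * a.yield_forage, rel=1e-9, abs=1e-12)
        assert b.n_mother_cows == pytest.approx(k * a.n_mother_cows, rel=1e-9, abs=1e-12)


class TestFixedPoint:
    def test_constant_curves_match_closed_form(self):
        fp = solve_fixed_point(
            GEOM, INPUTS, COEFF,
            RetentionCurve.constant(0.5), RetentionCurve.constant(0.6),
        )
        cf = solve_closed_form(GEOM, INPUTS, COEFF, 0.5, 0.6)
        assert fp.yield_vegetal == pytest.approx(cf.yield_vegetal, rel=1e-10)
        assert fp.yield_forage == pytest.approx(cf.yield_forage, rel=1e-10)
        assert fp.n_mother_cows == pytest.approx(cf.n_mother_cows, rel=1e-10)

    def test_saturating_curve_lowers_retention_at_high_input(self):
        """With a saturating forage curve, loading the forage subunit with
        more fixation lowers the realized retention fraction."""
        curve_v = RetentionCurve.constant(0.5)
        curve_f = RetentionCurve.saturating(rho_max=0.8, half_saturation=100.0)
        small = solve_fixed_point(
            GEOM, NitrogenInputs(10.0, 20.0, 20.0), COEFF, curve_v, curve_f
        )
        large = solve_fixed_point(
            GEOM, NitrogenInputs(10.0, 20.0, 400.0), COEFF, curve_v, curve_f
        )
        assert large.rho_forage < small.rho_forage
        # and each realized rho equals the curve evaluated at converged N
        led = large.flux_ledger["forage"]
        avail = led["deposition"] + led["fixation"] + led["manure"]
        assert large.rho_forage == pytest.approx(curve_f(avail), rel=1e-9)

    def test_zero_inputs_converge_immediately(self):
        sol = solve_fixed_point(
            GEOM, NitrogenInputs(0.0, 0.0, 0.0), COEFF,
            RetentionCurve.saturating(0.8, 100.0),
            RetentionCurve.saturating(0.8, 100.0),
        )
        assert sol.yield_vegetal == 0.0
        assert sol.n_mother_cows == 0.0

    def test_agrees_with_dense_grid_search_oracle(self):
        """Brute-force oracle: over a dense (rho_v, rho_f) grid, pick the
        most self-consistent pair (curve evaluated at the availabilities
        implied by that pair); the solver must land within one grid step."""
        curve_v = RetentionCurve.saturating(0.6, 80.0)
        curve_f = RetentionCurve.saturating(0.8, 150.0)
        geom = FarmGeometry(1.0, 0.5, gamma=0.7)
        inputs = NitrogenInputs(8.0, 30.0, 60.0)
        coeff = CyclingCoefficients(alpha=40.0, beta=0.004)

        grid = np.linspace(0.01, 0.8, 400)
        best, best_resid = None, np.inf
        for rv in grid:
            for rf in grid:
                try:
                    sol = solve_general_gamma(geom, inputs, coeff, rv, rf)
                except Exception:
                    continue
                led = sol.flux_ledger
                av = sum(led["vegetal"][k] for k in ("deposition", "fixation", "manure"))
                af = sum(led["forage"][k] for k in ("deposition", "fixation", "manure"))
                resid = abs(curve_v(av) - rv) + abs(curve_f(af) - rf)
                if resid < best_resid:
                    best, best_resid = (rv, rf), resid
        step = grid[1] - grid[0]
        sol = solve_fixed_point(geom, inputs, coeff, curve_v, curve_f)
        assert abs(sol.rho_vegetal - best[0]) <= step
        assert abs(sol.rho_forage - best[1]) <= step

    def test_reports_residual_on_non_convergence(self):
        with pytest.raises(ConvergenceError, match="residual"):
            solve_fixed_point(
                GEOM, INPUTS, COEFF,
                RetentionCurve.saturating(0.9, 50.0),
                RetentionCurve.saturating(0.9, 50.0),
                max_iter=2,
            )


class TestGammaSweep:
    def test_alpha_zero_gives_flat_sweep(self):
        coeff = CyclingCoefficients(alpha=0.0, beta=0.002)
        table = gamma_sweep(GEOM, INPUTS, coeff, 0.5, 0.6, n_points=5)
        assert table["yield_vegetal"].nunique() == 1

    def test_reference_parameters_increase_to_gamma_one(self):
        table = gamma_sweep(GEOM, INPUTS, COEFF, 0.5, 0.6, n_points=11)
        y = table["yield_vegetal"].to_numpy()
        assert (np.diff(y) > 0).all()
        assert table["gamma"].iloc[y.argmax()] == 1.0

    def test_two_points_are_the_endpoint_solutions(self):
        table = gamma_sweep(GEOM, INPUTS, COEFF, 0.5, 0.6, n_points=2)
        g0 = solve_general_gamma(
            FarmGeometry(1.0, 0.43, 0.0), INPUTS, COEFF, 0.5, 0.6
        )
        g1 = solve_closed_form(GEOM, INPUTS, COEFF, 0.5, 0.6)
        assert table["yield_vegetal"].iloc[0] == pytest.approx(g0.yield_vegetal)
        assert table["yield_vegetal"].iloc[1] == pytest.approx(g1.yield_vegetal)

    def test_rejects_degenerate_grid(self):
        with pytest.raises(ParameterError):
            gamma_sweep(GEOM, INPUTS, COEFF, 0.5, 0.6, n_points=1)


class TestValidation:
    def test_geometry_domain(self):
        with pytest.raises(ParameterError):
            FarmGeometry(area_vegetal=0.0)
        with pytest.raises(ParameterError):
            FarmGeometry(gamma=1.5)

    def test_negative_fluxes_rejected(self):
        with pytest.raises(ParameterError):
            NitrogenInputs(-1.0, 0.0, 0.0)

    def test_retention_curve_domain(self):
        with pytest.raises(ParameterError):
            RetentionCurve.constant(0.0)
        with pytest.raises(ParameterError):
            RetentionCurve.saturating(1.2, 100.0)
        with pytest.raises(ParameterError):
            RetentionCurve.saturating(0.5, 0.0)
        curve = RetentionCurve.saturating(0.8, 100.0)
        assert 0.0 < curve(1e6) < curve(0.0) <= 0.8
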