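"""ODE mean dynamics: frozen right-hand sides, the closed-form linear
oracle, RK4 order, and total-size conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetmap import dynamics as dyn
from hetmap.errors import DegenerateStateError, InvalidParameterError

# Linear "Given" parameter sets in genotype order QQ..q+q+.
LINEAR_SETS = [
    (0.12, 0.003, 0.006),
    (0.15, 0.027, 0.0011),
    (0.24, 0.05, 0.0007),
    (0.2, 0.015, 0.0009),
    (0.27, 0.018, 0.007),
    (0.3, 0.011, 0.003),
]


def naive_rk4(model, p, init, grid, w_convention="proportion"):
    """Textbook RK4 stepping, independent of the package implementation."""
    def rhs(y):
        if model == "linear":
            return np.array(dyn.linear_rhs((y[0], y[1]), p))
        return np.array(dyn.nonlinear_rhs((y[0], y[1]), p, w_convention))

    y = init.as_array().astype(float)
    h = grid.h
    out = []
    for g in grid.steps_per_gap():
        for _ in range(g):
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        out.append(y.copy())
    out = np.array(out)
    return np.concatenate([out[:, 0], out[:, 1]])


class TestRightHandSides:
    def test_linear_design_point(self):
        p = dyn.ODEParamsLinear(0.12, 0.003, 0.006)
        d = dyn.linear_rhs(dyn.State(1, 1), p)
        assert d == pytest.approx((0.123, 0.117), abs=1e-12)

    def test_nonlinear_design_point(self):
        p = dyn.ODEParamsNonlinear(0.12, 0.003, 0.0006, 0.66, 0.55)
        d = dyn.nonlinear_rhs(dyn.State(1, 1), p)
        assert d == pytest.approx((0.0626, 0.1774), abs=1e-12)

    def test_linear_decoupled(self):
        p = dyn.ODEParamsLinear(0.2, 0.0, 0.0)
        d = dyn.linear_rhs(dyn.State(2.0, 3.0), p)
        assert d == pytest.approx((0.4, 0.6))

    def test_nonlinear_reduces_to_linear(self):
        pl = dyn.ODEParamsLinear(0.15, 0.02, 0.01)
        pn = dyn.ODEParamsNonlinear(0.15, 0.02, 0.01, 0.0, 0.0)
        s = dyn.State(1.3, 0.4)
        assert dyn.nonlinear_rhs(s, pn) == pytest.approx(dyn.linear_rhs(s, pl))

    @given(
        x1=st.floats(0.01, 50), x2=st.floats(0.01, 50),
        r=st.floats(-0.5, 0.5), k1=st.floats(0, 1), k2=st.floats(0, 1),
        k3=st.floats(0, 1), k4=st.floats(0, 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_component_sum_is_growth_only(self, x1, x2, r, k1, k2, k3, k4):
        s = dyn.State(x1, x2)
        dl = dyn.linear_rhs(s, dyn.ODEParamsLinear(r, k1, k2))
        dn = dyn.nonlinear_rhs(s, dyn.ODEParamsNonlinear(r, k1, k2, k3, k4))
        assert dl[0] + dl[1] == pytest.approx(r * (x1 + x2), rel=1e-9, abs=1e-9)
        assert dn[0] + dn[1] == pytest.approx(r * (x1 + x2), rel=1e-9, abs=1e-9)

    def test_degenerate_state_raises(self):
        p = dyn.ODEParamsNonlinear(0.1, 0.01, 0.01, 0.5, 0.5)
        with pytest.raises(DegenerateStateError):
            dyn.nonlinear_rhs((0.0, 0.0), p)


class TestClosedForm:
    def test_identity_at_zero(self):
        p = dyn.ODEParamsLinear(0.12, 0.003, 0.006)
        s = dyn.linear_closed_form(p, dyn.State(1.7, 0.3), 0.0)
        assert (s.x1, s.x2) == pytest.approx((1.7, 0.3), abs=1e-14)

    def test_decoupled_exponential(self):
        p = dyn.ODEParamsLinear(0.2, 0.0, 0.0)
        s = dyn.linear_closed_form(p, dyn.State(1, 1), 5.0)
        assert s.x1 == pytest.approx(math.e, rel=1e-12)

    def test_fraction_limit(self):
        p = dyn.ODEParamsLinear(0.1, 0.03, 0.01)
        s = dyn.linear_closed_form(p, dyn.State(1, 1), 700.0)
        assert s.x1 / (s.x1 + s.x2) == pytest.approx(0.01 / 0.04, abs=1e-9)


class TestSolveRK4:
    def test_decoupled_exponential(self):
        grid = dyn.TimeGrid(times=(5.0,), h=0.05)
        mv = dyn.solve_rk4("linear", dyn.ODEParamsLinear(0.2, 0, 0),
                           dyn.State(1, 1), grid)
        assert mv[0] == pytest.approx(math.e, abs=1e-6)

    @pytest.mark.parametrize("params", LINEAR_SETS)
    def test_matches_closed_form(self, params):
        p = dyn.ODEParamsLinear(*params)
        grid = dyn.TimeGrid()
        mv = dyn.solve_rk4("linear", p, dyn.State(1, 1), grid)
        exact = np.array(
            [
                [dyn.linear_closed_form(p, dyn.State(1, 1), t).x1,
                 dyn.linear_closed_form(p, dyn.State(1, 1), t).x2]
                for t in grid.times
            ]
        )
        exact = np.concatenate([exact[:, 0], exact[:, 1]])
        assert np.abs(mv - exact).max() < 1e-6

    @pytest.mark.parametrize("model,params", [
        ("linear", (0.12, 0.003, 0.006)),
        ("nonlinear", (0.12, 0.003, 0.0006, 0.66, 0.55)),
    ])
    def test_matches_naive_stepping(self, model, params):
        p = dyn.params_from_array(model, params)
        grid = dyn.TimeGrid()
        mv = dyn.solve_rk4(model, p, dyn.State(1, 1), grid)
        ref = naive_rk4(model, p, dyn.State(1, 1), grid)
        assert np.abs(mv - ref).max() < 1e-12

    def test_nonlinear_total_conservation(self):
        p = dyn.ODEParamsNonlinear(0.12, 0.003, 0.0006, 0.66, 0.55)
        grid = dyn.TimeGrid()
        mv = dyn.solve_rk4("nonlinear", p, dyn.State(1, 1), grid)
        total = mv[:9] + mv[9:]
        expected = 2 * np.exp(0.12 * np.array(grid.times))
        assert np.abs(total - expected).max() < 1e-6

    def test_fourth_order_convergence(self):
        p = dyn.ODEParamsLinear(0.12, 0.003, 0.006)

        def err(h):
            grid = dyn.TimeGrid(times=(9.0,), h=h)
            mv = dyn.solve_rk4("linear", p, dyn.State(1, 1), grid)
            s = dyn.linear_closed_form(p, dyn.State(1, 1), 9.0)
            return np.abs(mv - [s.x1, s.x2]).max()

        ratio = err(0.6) / err(0.3)
        assert 8 < ratio < 32  # halving h cuts the error ~16x

    def test_nonlinear_zero_feedback_equals_linear(self):
        grid = dyn.TimeGrid()
        pl = dyn.ODEParamsLinear(0.15, 0.02, 0.01)
        pn = dyn.ODEParamsNonlinear(0.15, 0.02, 0.01, 0.0, 0.0)
        a = dyn.solve_rk4("linear", pl, dyn.State(1, 1), grid)
        b = dyn.solve_rk4("nonlinear", pn, dyn.State(1, 1), grid)
        assert np.abs(a - b).max() < 1e-12


class TestMeanVector:
    def test_single_time_layout(self):
        grid = dyn.TimeGrid(times=(1.0,), h=0.05)
        mv = dyn.mean_vector("linear", dyn.ODEParamsLinear(0.1, 0.01, 0.01),
                             dyn.State(1, 1), grid)
        assert mv.shape == (2,)

    def test_variable_major_layout(self):
        grid = dyn.TimeGrid(times=(1.0, 2.0), h=0.05)
        p = dyn.ODEParamsLinear(0.3, 0.0, 0.0)
        mv = dyn.mean_vector("linear", p, dyn.State(2.0, 1.0), grid)
        # x1 entries first (growing from 2), then x2 (growing from 1)
        assert mv[0] == pytest.approx(2 * math.exp(0.3), abs=1e-6)
        assert mv[2] == pytest.approx(1 * math.exp(0.3), abs=1e-6)

    def test_six_design_curves_distinct(self):
        grid = dyn.TimeGrid()
        curves = [
            dyn.mean_vector("linear", dyn.ODEParamsLinear(*ps),
                            dyn.State(1, 1), grid)
            for ps in LINEAR_SETS
        ]
        for i in range(6):
            for j in range(i + 1, 6):
                assert np.abs(curves[i] - curves[j]).max() > 0


class TestTimeGrid:
    def test_bad_substep_rejected(self):
        with pytest.raises(InvalidParameterError):
            dyn.TimeGrid(times=(1.0, 2.0), h=0.3)

    def test_non_increasing_rejected(self):
        with pytest.raises(InvalidParameterError):
            dyn.TimeGrid(times=(2.0, 1.0), h=0.05)

    def test_default_design(self):
        grid = dyn.TimeGrid()
        assert grid.T == 9 and grid.h == 0.05 and grid.times[0] == 1.0
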