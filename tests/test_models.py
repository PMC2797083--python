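"""Unit drifts, curvature bounds and trajectory radii."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from syncnoise.models import (
    FN_DEFAULT_PARAMS,
    HR_DEFAULT_PARAMS,
    InvalidInputError,
    OscillatorModel,
    fitzhugh_nagumo,
    fn_drift,
    hessian_bound,
    hindmarsh_rose,
    hr_drift,
    linear_drift,
    linear_model,
    trajectory_radius,
)

finite_floats = st.floats(-5.0, 5.0, allow_nan=False)


class TestFNDrift:
    def test_cubic_component_vanishes_at_zero_voltage(self):
        # at v = 0 the drift reduces to its linear part exactly
        p = FN_DEFAULT_PARAMS
        for w in (-1.0, 0.0, 2.5):
            d = fn_drift(np.array([0.0, w]), 0.0)
            assert d[0] == p["c"] * (w + p["I"])
            assert d[1] == -(0.0 - p["a"] + p["b"] * w) / p["c"]

    def test_equilibrium_found_by_root_finder_gives_zero_drift(self):
        # independent oracle: reduce the 2-d fixed point to a scalar root
        # problem (w = (a - v)/b from the recovery nullcline) and bisect
        p = FN_DEFAULT_PARAMS
        a, b, c, bias = p["a"], p["b"], p["c"], p["I"]

        def g(v):
            return v + (a - v) / b - v**3 / 3.0 + bias

        v_star = brentq(g, -3.0, 3.0, xtol=1e-14)
        w_star = (a - v_star) / b
        d = fn_drift(np.array([v_star, w_star]), 0.0)
        assert np.max(np.abs(d)) < 1e-10

    @given(v=finite_floats, w=finite_floats, delta=finite_floats)
    def test_input_shifts_voltage_equation_exactly(self, v, w, delta):
        base = fn_drift(np.array([v, w]), 0.0, input=0.0)
        shifted = fn_drift(np.array([v, w]), 0.0, input=delta)
        assert shifted[0] - base[0] == pytest.approx(delta, abs=1e-12)
        assert shifted[1] == base[1]

    def test_missing_parameter_and_nonfinite_state_raise(self):
        with pytest.raises(InvalidInputError, match="'c'"):
            fn_drift(np.zeros(2), 0.0, params={"a": 0.7, "b": 0.8, "I": 0.0})
        with pytest.raises(InvalidInputError, match="non-finite"):
            fn_drift(np.array([np.nan, 0.0]), 0.0)


class TestHRDrift:
    def test_matches_symbolic_polynomial_at_integer_states(self):
        # independent oracle: exact rational evaluation of the polynomial
        # right-hand side via sympy
        import sympy as sp

        x, y, z = sp.symbols("x y z")
        p = {k: sp.Rational(str(v)) for k, v in HR_DEFAULT_PARAMS.items()}
        exprs = [
            y - p["a"] * x**3 + p["b"] * x**2 - z + p["I"],
            p["c"] - p["d"] * x**2 - y,
            p["r"] * (p["s"] * (x - p["x_rest"]) - z),
        ]
        for state in [(-2, 0, 1), (1, -1, 2), (3, 2, -1), (0, 0, 0)]:
            expected = [float(e.subs({x: state[0], y: state[1], z: state[2]})) for e in exprs]
            got = hr_drift(np.array(state, dtype=float), 0.0)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    @given(
        s=st.tuples(finite_floats, finite_floats, finite_floats),
        delta=finite_floats,
    )
    def test_input_enters_first_component_only(self, s, delta):
        state = np.array(s)
        diff = hr_drift(state, 0.0, input=delta) - hr_drift(state, 0.0)
        assert diff[0] == pytest.approx(delta, abs=1e-12)
        assert diff[1] == 0.0 and diff[2] == 0.0

    def test_time_invariance_with_constant_input(self):
        state = np.array([0.3, -0.2, 1.1])
        np.testing.assert_array_equal(
            hr_drift(state, 0.0, input=1.5), hr_drift(state, 100.0, input=1.5)
        )


class TestLinearDrift:
    def test_zero_system(self):
        out = linear_drift(np.array([1.0, -2.0]), 0.0, np.zeros((2, 2)), np.zeros(2))
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_scalar_ou(self):
        a = 1.7
        assert linear_drift(np.array([2.0]), 0.0, np.array([[-a]]))[0] == -a * 2.0

    @given(
        x=st.tuples(finite_floats, finite_floats),
        y=st.tuples(finite_floats, finite_floats),
    )
    def test_affine_superposition(self, x, y):
        A = np.array([[0.5, -1.0], [2.0, 0.25]])
        b = np.array([0.3, -0.7])
        x, y = np.array(x), np.array(y)
        lhs = linear_drift(x + y, 0.0, A, b)
        rhs = linear_drift(x, 0.0, A, b) + linear_drift(y, 0.0, A, b) - b
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidInputError):
            linear_drift(np.array([1.0, 2.0, 3.0]), 0.0, np.zeros((2, 2)))


class TestHessianBound:
    def test_linear_model_is_exactly_zero(self):
        m = linear_model(np.array([[-1.0, 2.0], [0.0, -3.0]]))
        for radius in (0.0, 1.0, 100.0):
            assert hessian_bound(m, radius) == 0.0

    def test_fn_zero_radius(self, fn_model):
        assert hessian_bound(fn_model, 0.0) == 0.0

    def test_fn_radius_one_matches_grid_search_oracle(self, fn_model):
        # brute force: largest |d^2 f_v / dv^2| = |-2 c v| over |v| <= 1,
        # estimated by central differences on a fine grid
        c = fn_model.params["c"]
        grid = np.linspace(-1.0, 1.0, 2001)
        h = 1e-5
        second = np.abs(
            (
                fn_drift(np.stack([grid + h, np.zeros_like(grid)], axis=1), 0.0)[:, 0]
                - 2 * fn_drift(np.stack([grid, np.zeros_like(grid)], axis=1), 0.0)[:, 0]
                + fn_drift(np.stack([grid - h, np.zeros_like(grid)], axis=1), 0.0)[:, 0]
            )
            / h**2
        )
        oracle = second.max()
        assert hessian_bound(fn_model, 1.0) == pytest.approx(oracle, rel=1e-4)
        assert hessian_bound(fn_model, 1.0) == pytest.approx(2.0 * c, rel=1e-12)

    @pytest.mark.parametrize("factory", [fitzhugh_nagumo, hindmarsh_rose])
    def test_nondecreasing_in_radius(self, factory):
        m = factory()
        values = [hessian_bound(m, r) for r in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_negative_radius_rejected(self, fn_model):
        with pytest.raises(InvalidInputError):
            hessian_bound(fn_model, -0.1)

    def test_finite_difference_fallback_on_user_model(self):
        # drift (sin x1, x2^2) has per-component Hessian norms |sin| <= 1
        # and 2; the fallback should find ~2 on any ball
        m = OscillatorModel(
            name="user",
            state_dim=2,
            params={},
            noise_mask=(True, True),
            coupling_mask=(True, True),
            input_mask=(True, False),
            drift_fn=lambda x, t, u, p: np.stack(
                [np.sin(x[..., 0]), x[..., 1] ** 2], axis=-1
            ),
        )
        assert hessian_bound(m, 2.0) == pytest.approx(2.0, rel=1e-2)


class TestTrajectoryRadius:
    def test_trivial_cases(self):
        zeros = np.zeros((5, 3, 2))
        assert trajectory_radius(zeros) == 0.0
        const = np.full((4, 1, 2), -2.5)
        assert trajectory_radius(const) == 2.5

    def test_matches_exhaustive_scan_on_fn_limit_cycle(self, fn_reference):
        # oracle: brute-force scan of the stored array
        oracle = 0.0
        arr = fn_reference.states
        for ti in range(arr.shape[0]):
            for oi in range(arr.shape[1]):
                oracle = max(oracle, abs(arr[ti, oi, 0]))
        assert trajectory_radius(fn_reference) == pytest.approx(oracle, rel=0, abs=0)

    def test_component_selection(self, rng):
        arr = rng.normal(size=(10, 2, 3))
        assert trajectory_radius(arr, components=[1]) == np.abs(arr[:, :, 1]).max()

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            trajectory_radius(np.empty((0, 1, 2)))
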