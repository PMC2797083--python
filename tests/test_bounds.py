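"""Theoretical bound expressions: limits, monotonicity, consistency."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from syncnoise.bounds import (
    DegenerateTransformError,
    LargeCouplingWarning,
    eigenmode_transform,
    mean_impact_bound,
    pair_bound,
    sync_bound_all_to_all,
    taylor_mismatch,
)
from syncnoise.models import (
    InvalidInputError,
    OscillatorModel,
    linear_drift,
    linear_model,
)
from syncnoise.simulate import SimConfig, simulate_noise_free


class TestSyncBound:
    def test_noise_free_networks_synchronize_completely(self):
        assert sync_bound_all_to_all(10, 50.0, 0.0).bound_value == 0.0

    def test_strictly_decreasing_in_k_with_inverse_k_asymptote(self):
        b1 = sync_bound_all_to_all(8, 40.0, 0.5)
        b2 = sync_bound_all_to_all(8, 80.0, 0.5)
        assert b2.bound_value < b1.bound_value
        assert b1.asymptotic_value / b2.asymptotic_value == pytest.approx(2.0)

    def test_vanishes_in_strong_coupling_limit(self):
        values = [sync_bound_all_to_all(6, k, 1.0).bound_value for k in (1e2, 1e5, 1e8)]
        assert values[0] > values[1] > values[2]
        assert values[-1] < 1e-6

    def test_proportional_to_sigma_squared(self):
        lo = sync_bound_all_to_all(4, 50.0, 0.3).bound_value
        hi = sync_bound_all_to_all(4, 50.0, 0.6).bound_value
        assert hi / lo == pytest.approx(4.0)

    def test_weak_coupling_warns(self):
        with pytest.warns(LargeCouplingWarning):
            sync_bound_all_to_all(4, 5.0, 0.5)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            sync_bound_all_to_all(1, 50.0, 0.5)
        with pytest.raises(InvalidInputError):
            sync_bound_all_to_all(4, 0.0, 0.5)
        with pytest.raises(InvalidInputError):
            sync_bound_all_to_all(4, 50.0, -0.1)


class TestPairBound:
    def test_zero_noise(self):
        assert pair_bound(40.0, 0.0).bound_value == 0.0

    def test_consistent_with_general_bound_at_two_oscillators(self):
        # the n=2 network bound counts the single pair in both orders
        k, sigma = 60.0, 0.4
        assert sync_bound_all_to_all(2, k, sigma).bound_value == pytest.approx(
            2.0 * pair_bound(k, sigma).bound_value
        )

    def test_pair_decomposition_reproduces_general_bound(self):
        # in the all-to-all pair decomposition each pair difference feels
        # damping n*k; summing that per-pair bound over the n(n-1)
        # ordered pairs must give the network bound exactly
        n, k, sigma = 6, 30.0, 0.5
        per_pair = pair_bound(n * k / 2.0, sigma).bound_value
        total = sync_bound_all_to_all(n, k, sigma).bound_value
        assert total == pytest.approx(n * (n - 1) * per_pair)

    def test_nonincreasing_on_doubling_grid(self):
        values = [pair_bound(k, 0.5).bound_value for k in (2.0, 4.0, 8.0, 16.0, 32.0)]
        assert all(b <= a for a, b in zip(values, values[1:]))

    def test_coupling_below_validity_threshold_rejected(self):
        # 2k must exceed the fast drift scale c for contraction to hold
        with pytest.raises(InvalidInputError):
            pair_bound(1.0, 0.5)


class TestEigenmodeTransform:
    @given(st.integers(0, 10**6))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        pair = rng.normal(size=(2, 2))
        tr = eigenmode_transform(pair, k=25.0)
        np.testing.assert_allclose(tr.inverse(), pair[0] - pair[1], atol=1e-12)

    def test_identical_states_have_zero_modes(self):
        state = np.array([0.3, -0.8])
        tr = eigenmode_transform(np.stack([state, state]), k=25.0)
        np.testing.assert_allclose(tr.modes, 0.0, atol=1e-14)

    def test_mode_decay_rates_match_simulated_linear_system(self):
        # simulate the frozen pair-difference system and fit the decay of
        # each modal coordinate; rates must match the eigenvalues
        k = 25.0
        tr = eigenmode_transform(np.array([[1.0, -0.5], [0.0, 0.0]]), k=k)
        from syncnoise.bounds import _pair_evolution_matrix
        from syncnoise.models import FN_DEFAULT_PARAMS

        A = _pair_evolution_matrix(FN_DEFAULT_PARAMS, k, 0.0)
        model = linear_model(A)
        cfg = SimConfig(dt=2e-5, t_end=0.05, seed=0)
        traj = simulate_noise_free(model, None, np.array([1.0, -0.5]), cfg)
        modes = np.linalg.solve(tr.eigenvectors, traj.states[:, 0, :].T)
        for mode_idx, lam in enumerate(tr.eigenvalues):
            series = np.abs(modes[mode_idx])
            sel = series > 1e-12 * series[0]
            # keep a window where this mode still dominates numerically
            tt = traj.times[sel][:1500]
            yy = np.log(series[sel][:1500])
            slope = np.polyfit(tt, yy, 1)[0]
            assert slope == pytest.approx(lam, rel=0.05)

    def test_degenerate_regime_raises(self):
        # weak coupling gives complex (spiral) modes: no real diagonalization
        with pytest.raises(DegenerateTransformError):
            eigenmode_transform(np.zeros((2, 2)), k=1.4, q=0.0)


def scalar_cubic_model() -> OscillatorModel:
    return OscillatorModel(
        name="scalar_cubic",
        state_dim=1,
        params={},
        noise_mask=(True,),
        coupling_mask=(True,),
        input_mask=(True,),
        drift_fn=lambda x, t, u, p: x - x**3 / 3.0,
        hessian_norm_fn=lambda r, p: 2.0 * r,
    )


class TestTaylorMismatch:
    def test_identical_states(self, fn_model):
        states = np.tile([[0.5, -0.2]], (4, 1))
        mism, bound = taylor_mismatch(fn_model, states, Q=10.0)
        assert mism == pytest.approx(0.0, abs=1e-14)
        assert bound == pytest.approx(0.0, abs=1e-14)

    def test_linear_dynamics_contribute_no_mismatch(self, rng):
        model = linear_model(np.array([[-1.0, 0.5], [0.2, -2.0]]), np.array([0.1, -0.3]))
        states = rng.normal(size=(7, 2))
        mism, bound = taylor_mismatch(model, states, Q=0.0)
        assert mism < 1e-12
        assert bound == 0.0

    def test_scalar_cubic_hand_computed_example(self):
        # f(v) = v - v^3/3 at states {0, 1}: mean drift 1/3, drift at the
        # mean 0.5 - 1/24, mismatch exactly 0.125; bound = (2/2)*0.25
        model = scalar_cubic_model()
        states = np.array([[0.0], [1.0]])
        mism, bound = taylor_mismatch(model, states, Q=2.0)
        assert mism == pytest.approx(0.125, abs=1e-12)
        assert bound == pytest.approx(0.25, abs=1e-12)
        assert mism <= bound

    def test_radius_violation_rejected(self):
        model = scalar_cubic_model()
        with pytest.raises(InvalidInputError):
            taylor_mismatch(model, np.array([[0.0], [2.0]]), Q=2.0, radius=1.0)


class TestMeanImpactBound:
    def test_zero_curvature_zero_noise(self):
        assert mean_impact_bound(0.0, 1.0, 0.0, 5) == 0.0

    def test_inverse_square_root_scaling_for_linear_dynamics(self):
        one = mean_impact_bound(0.0, 0.0, 1.0, 1)
        four = mean_impact_bound(0.0, 0.0, 1.0, 4)
        assert one / four == pytest.approx(2.0)

    def test_vanishes_jointly_in_n_and_sync_error(self):
        values = [
            mean_impact_bound(3.0, c, 1.0, n)
            for c, n in [(1.0, 10), (0.1, 100), (0.01, 1000)]
        ]
        assert values[0] > values[1] > values[2]
        assert values[-1] < 0.05

    def test_negative_inputs_rejected(self):
        for args in [(-1, 1, 1, 2), (1, -1, 1, 2), (1, 1, -1, 2), (1, 1, 1, 0)]:
            with pytest.raises(InvalidInputError):
                mean_impact_bound(*args)
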