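"""Unit and property tests for the three-compartment transport model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermakin import (
    ObservationMode,
    RateParameters,
    Trajectory,
    compute_derivative,
    observe,
    simulate_closed_form,
    simulate_numeric,
    steady_state,
    system_matrices,
)
from conftest import random_positive_params

rates = st.floats(1e-3, 1e2, allow_nan=False, allow_infinity=False)
states = st.floats(0.0, 1e3, allow_nan=False, allow_infinity=False)


class TestRateParameters:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            RateParameters(1, -0.1, 1, 1)
        with pytest.raises(ValueError):
            RateParameters(np.nan, 1, 1, 1)
        with pytest.raises(ValueError):
            RateParameters(np.inf, 1, 1, 1)

    def test_array_round_trip(self):
        k = RateParameters(0.5, 2, 1, 3)
        assert RateParameters.from_array(k.as_array()) == k


class TestDerivative:
    @pytest.mark.parametrize(
        "params, state, expected",
        [
            # only inflow active
            ((1, 0, 0, 0), (0, 0, 0), (1, 0, 0)),
            # uniform state under pure diffusion: zero net flux
            ((0, 1, 0, 0), (1, 1, 1), (0, 0, 0)),
            # hand substitution into the rate equations
            ((0.5, 2, 1, 3), (1, 2, 3), (1.5, -1, -9)),
        ],
    )
    def test_known_values(self, params, state, expected):
        d = compute_derivative(state, RateParameters(*params))
        np.testing.assert_allclose(d, expected, rtol=0, atol=1e-14)

    def test_rejects_nonfinite_state(self):
        with pytest.raises(ValueError):
            compute_derivative((1, np.nan, 0), RateParameters(1, 1, 1, 1))

    @given(kin=rates, kd=rates, kc=rates, ko=rates,
           x=st.tuples(states, states, states))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_balance_identity(self, kin, kd, kc, ko, x):
        """Summing the three equations leaves only inflow minus outflow."""
        p = RateParameters(kin, kd, kc, ko)
        d = compute_derivative(x, p)
        np.testing.assert_allclose(
            d.sum(), kin - ko * x[2], rtol=1e-10, atol=1e-9
        )


class TestSystemMatrices:
    def test_zero_params(self):
        A, b = system_matrices(RateParameters(0, 0, 0, 0))
        assert not A.any() and not b.any()

    def test_unit_rates_matrix(self):
        A, b = system_matrices(RateParameters(1, 1, 1, 1))
        np.testing.assert_array_equal(A, [[-2, 1, 0], [2, -3, 1], [0, 2, -2]])
        np.testing.assert_array_equal(b, [1, 0, 0])

    def test_consistent_with_derivative(self, rng):
        p = random_positive_params(rng)
        A, b = system_matrices(p)
        for _ in range(10):
            x = rng.uniform(0, 10, 3)
            np.testing.assert_allclose(
                compute_derivative(x, p), A @ x + b, rtol=1e-12
            )

    def test_metzler_and_stable(self, rng):
        """Off-diagonals nonnegative; strictly positive rates give a Hurwitz
        matrix (all eigenvalues in the open left half plane)."""
        for _ in range(20):
            p = random_positive_params(rng)
            A, _ = system_matrices(p)
            off = A[~np.eye(3, dtype=bool)]
            assert np.all(off >= 0)
            assert np.all(np.linalg.eigvals(A).real < 0)


class TestSimulation:
    def test_all_zero_params_constant_trajectory(self, grid_6h):
        traj = simulate_closed_form(RateParameters(0, 0, 0, 0), (1, 2, 3), grid_6h)
        np.testing.assert_array_equal(traj.states, np.tile([1, 2, 3], (13, 1)))

    def test_pure_inflow_is_linear_in_time(self, grid_6h):
        traj = simulate_closed_form(RateParameters(1, 0, 0, 0), (0, 0, 0), grid_6h)
        np.testing.assert_allclose(traj.states[:, 0], grid_6h, rtol=1e-12)

    def test_zero_input_zero_state_stays_zero(self, grid_6h):
        traj = simulate_numeric(RateParameters(0, 1, 1, 1), (0, 0, 0), grid_6h)
        np.testing.assert_allclose(traj.states, 0.0, atol=1e-12)

    def test_converges_to_steady_state(self, grid_6h):
        p = RateParameters(1, 1, 1, 1)
        traj = simulate_closed_form(p, (0, 0, 0), np.array([0.0, 100.0]))
        np.testing.assert_allclose(traj.states[-1], (1, 1, 1), rtol=1e-9)

    def test_closed_form_matches_numeric(self, rng, grid_6h):
        for _ in range(20):
            p = random_positive_params(rng)
            a = simulate_closed_form(p, (0, 0, 0), grid_6h).states
            b = simulate_numeric(p, (0, 0, 0), grid_6h, rtol=1e-12, atol=1e-12).states
            scale = max(np.max(np.abs(a)), 1e-30)
            assert np.max(np.abs(a - b)) / scale < 1e-8

    def test_nonnegative_and_monotone_observable(self, rng, grid_6h):
        """From the drug-free state the receptor signal only accumulates."""
        for _ in range(50):
            p = random_positive_params(rng)
            traj = simulate_closed_form(p, (0, 0, 0), grid_6h)
            assert traj.states.min() >= -1e-9
            assert np.all(np.diff(traj.x3) >= -1e-9 * max(traj.x3.max(), 1))

    def test_linearity_in_inflow(self, rng, grid_6h):
        """Doubling k_in doubles the whole trajectory (zero initial state)."""
        p = random_positive_params(rng)
        t1 = simulate_closed_form(p, (0, 0, 0), grid_6h).states
        t2 = simulate_closed_form(p.scaled(2.0), (0, 0, 0), grid_6h).states
        np.testing.assert_allclose(t2, 2 * t1, rtol=1e-9, atol=1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_closed_form(RateParameters(1, 1, 1, 1), (0, 0, 0), [0.0, 0.0, 1.0])


class TestSteadyState:
    def test_zero_inflow(self):
        np.testing.assert_array_equal(
            steady_state(RateParameters(0, 1, 1, 1)), (0, 0, 0)
        )

    def test_receptor_level_is_inflow_over_outflow(self):
        # mass balance: k_out * x3* = k_in regardless of transport rates
        ss = steady_state(RateParameters(2, 0.7, 1.3, 4))
        assert ss[2] == pytest.approx(0.5, rel=1e-12)

    def test_unit_rates(self):
        np.testing.assert_allclose(
            steady_state(RateParameters(1, 1, 1, 1)), (1, 1, 1), rtol=1e-12
        )

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError, match="k_out"):
            steady_state(RateParameters(1, 1, 1, 0))
        with pytest.raises(ValueError, match="k_d"):
            steady_state(RateParameters(1, 0, 0, 1))


class TestObserve:
    def test_direct_mode_returns_third_state(self, rng, grid_6h):
        p = random_positive_params(rng)
        traj = simulate_closed_form(p, (0, 0, 0), grid_6h)
        obs = observe(traj, ObservationMode.DIRECT)
        np.testing.assert_array_equal(obs.values, traj.states[:, 2])

    def test_cumulative_outflow_of_constant_level(self, grid_6h):
        p = RateParameters(1, 1, 1, 2)
        states = np.tile([0.0, 0.0, 3.0], (grid_6h.size, 1))
        traj = Trajectory(times=grid_6h, states=states, params=p)
        obs = observe(traj, "cumulative_outflow")
        # constant receptor level c: integral of k_out*c over [0, T]
        assert obs.values[-1] == pytest.approx(2 * 3.0 * 6.0, rel=1e-12)

    def test_cumulative_outflow_nondecreasing(self, rng, grid_6h):
        for _ in range(10):
            p = random_positive_params(rng)
            traj = simulate_closed_form(p, (0, 0, 0), grid_6h)
            obs = observe(traj, ObservationMode.CUMULATIVE_OUTFLOW)
            assert np.all(np.diff(obs.values) >= 0)

    def test_unknown_mode_rejected(self, grid_6h):
        traj = simulate_closed_form(RateParameters(1, 1, 1, 1), (0, 0, 0), grid_6h)
        with pytest.raises(ValueError):
            observe(traj, "something-else")
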