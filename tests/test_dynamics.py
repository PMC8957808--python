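"""Leaky-integrator dynamics: activation, Euler updates, fixed points."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import socialfear as sf
from socialfear import (
    ConfigurationError,
    NetworkState,
    SimParams,
    SimulationDivergence,
    activation,
    euler_step,
    run_timesteps,
)


class TestActivation:
    @pytest.mark.parametrize(
        "v,expected",
        [
            (0.0, 0.0),
            (-5.0, 0.0),  # negative voltages rectify to zero
            (1.0, math.tanh(1.0)),  # ~0.7616, the unrectified branch
        ],
    )
    def test_pointwise_values(self, v, expected):
        assert activation(v) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-12, 12))
    def test_bounded_and_monotone(self, v):
        f = activation(v)
        assert 0.0 <= f < 1.0
        assert activation(v + 0.5) >= f

    def test_vector_input(self):
        out = activation(np.array([-1.0, 0.0, 2.0]))
        assert out.shape == (3,)
        assert out[0] == 0.0 and out[2] == pytest.approx(math.tanh(2.0))

    def test_non_finite_input_raises(self):
        with pytest.raises(SimulationDivergence):
            activation(float("nan"))


class TestSimParams:
    def test_defaults(self):
        p = SimParams()
        assert p.trial_length == 500 and p.leak == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(dt=0.0), dict(tau=-1.0), dict(trial_length=0), dict(dt=2.0, tau=1.0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimParams(**kwargs)


class TestEulerStep:
    def test_full_leak_replaces_voltage(self):
        # dt = tau: V_new = I + W @ F(V) exactly
        params = SimParams(dt=1.0, tau=1.0)
        W = np.array([[0.0, 0.5], [0.3, 0.0]])
        state = NetworkState(V=np.array([1.0, -0.5]), F=activation([1.0, -0.5]), W=W)
        I = np.array([0.2, 0.1])
        new = euler_step(state, I, params)
        assert np.allclose(new.V, I + W @ state.F)

    def test_pure_geometric_leak(self):
        params = SimParams(dt=0.1, tau=1.0)
        state = NetworkState.zeros(1)
        state.V[:] = 1.0
        state.F[:] = 0.0  # rate zeroed so only the leak acts
        new = euler_step(state, np.zeros(1), params)
        assert new.V[0] == pytest.approx(0.9)

    def test_dimension_mismatch_is_config_error(self):
        state = NetworkState.zeros(3)
        with pytest.raises(ConfigurationError):
            euler_step(state, np.zeros(2), SimParams())

    def test_divergence_names_unit(self):
        state = NetworkState.zeros(2)
        state.V[1] = 1.0
        state.F[1] = 1.0
        state.W[1, 1] = 1.7e308
        bad_I = np.array([0.0, 1.7e308])
        with np.errstate(over="ignore"):
            with pytest.raises(SimulationDivergence, match="unitB"):
                euler_step(state, bad_I, SimParams(dt=1.0), names=["unitA", "unitB"])


def _fixed_point_oracle(W, I, tol=1e-12, iters=100000):
    """Independent damped fixed-point iteration of V = I + W @ F(V)."""
    V = np.zeros(len(I))
    for _ in range(iters):
        V_new = 0.5 * V + 0.5 * (I + W @ np.maximum(np.tanh(V), 0.0))
        if np.max(np.abs(V_new - V)) < tol:
            return V_new
        V = V_new
    raise RuntimeError("oracle did not converge")


class TestRunTimesteps:
    def test_single_step_matches_euler_step(self):
        params = SimParams()
        rngW = np.random.default_rng(7).normal(scale=0.4, size=(4, 4))
        state = NetworkState.zeros(4, rngW)
        I = np.array([0.5, 0.0, 0.2, 0.0])
        one = euler_step(state, I, params)
        final, trace = run_timesteps(state, I, params, n=1)
        assert np.array_equal(final.V, one.V)
        assert np.array_equal(trace[0], one.F)

    def test_zero_input_zero_trace(self):
        W = np.random.default_rng(3).normal(size=(5, 5))
        state = NetworkState.zeros(5, W)
        _, trace = run_timesteps(state, np.zeros(5), SimParams(), n=500)
        assert np.all(trace == 0.0)

    def test_deterministic_repeatability(self):
        W = np.random.default_rng(11).normal(scale=0.3, size=(6, 6))
        I = np.linspace(0, 1, 6)
        t1 = run_timesteps(NetworkState.zeros(6, W), I, SimParams(), 300)[1]
        t2 = run_timesteps(NetworkState.zeros(6, W), I, SimParams(), 300)[1]
        assert np.array_equal(t1, t2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_fixed_point_matches_independent_oracle(self, seed):
        """Long-run state under constant input solves V = I + W F(V)."""
        rng = np.random.default_rng(seed)
        n = 5
        W = rng.normal(scale=0.3, size=(n, n))
        np.fill_diagonal(W, 0.0)
        I = rng.uniform(0, 1, size=n)
        expected = _fixed_point_oracle(W, I)
        final, _ = run_timesteps(NetworkState.zeros(n, W), I, SimParams(), 3000)
        assert np.max(np.abs(final.V - expected)) < 1e-6

    def test_leak_only_monotone_decay(self):
        state = NetworkState.zeros(1)
        state.V[0] = 2.0
        _, trace = run_timesteps(state, np.zeros(1), SimParams(), 200)
        V = np.concatenate([[2.0], 2.0 * 0.9 ** np.arange(1, 201)])
        f = np.maximum(np.tanh(V[1:]), 0)
        assert np.allclose(trace[:, 0], f)
        assert np.all(np.diff(trace[:, 0]) <= 0)

    def test_rate_bounds_on_shipped_run(self, basic_result):
        for rec in basic_result.trials:
            assert rec.trace.min() >= 0.0
            assert rec.trace.max() < 1.0
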