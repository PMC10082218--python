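"""Delay-loop dynamics: masking, stepping, fading memory, spike train."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respirc import (
    InvalidParameterError,
    RCParams,
    ShapeError,
    make_mask,
    run_reservoir,
    spike_train_response,
    state_for_index,
    step_desynchronized,
    step_synchronized,
    windowed_states,
)
from respirc.reservoir import quiescent_state

from conftest import slot_stream_oracle


class TestMask:
    def test_deterministic_for_fixed_seed(self):
        a = make_mask(12, "binary", seed=7)
        b = make_mask(12, "binary", seed=7)
        np.testing.assert_array_equal(a, b)

    def test_binary_support(self):
        m = make_mask(12, "binary", seed=3)
        assert set(np.unique(m)) <= {-1.0, 1.0}

    def test_uniform_support_and_mean(self):
        m = make_mask(1000, "uniform", seed=1)
        assert np.all((m >= -1) & (m <= 1))
        assert abs(m.mean()) < 0.1  # law of large numbers

    @pytest.mark.parametrize("bad", [0, -3])
    def test_rejects_nonpositive_size(self, bad):
        with pytest.raises(InvalidParameterError):
            make_mask(bad)

    def test_rejects_unknown_kind(self):
        with pytest.raises(InvalidParameterError):
            make_mask(5, "gaussian")  # type: ignore[arg-type]


class TestStepSynchronized:
    def test_closed_form_no_feedback(self):
        p = RCParams(alpha=0.0, beta=1.0, phi=0.0)
        mask = np.ones(p.n_active)
        x = step_synchronized(np.zeros(p.n_active), 0.5, p, mask=mask)
        np.testing.assert_allclose(x, np.sin(0.5))

    def test_zero_drive_gives_zero_state(self):
        p = RCParams(alpha=0.0, beta=0.0, phi=0.0)
        x = step_synchronized(np.linspace(-1, 1, p.n_active), 0.3, p)
        np.testing.assert_array_equal(x, np.zeros(p.n_active))

    def test_matches_elementwise_oracle(self, p_default):
        rng = np.random.default_rng(2)
        x_prev = rng.uniform(-1, 1, p_default.n_active)
        u = rng.uniform(-1, 1)
        mask = p_default.mask()
        expected = np.array(
            [
                np.sin(p_default.alpha * x_prev[i] + p_default.beta * mask[i] * u
                       + p_default.phi)
                for i in range(p_default.n_active)
            ]
        )
        got = step_synchronized(x_prev, u, p_default)
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-15)

    def test_shape_mismatch_raises(self, p_default):
        with pytest.raises(ShapeError):
            step_synchronized(np.zeros(5), 0.1, p_default)


class TestStepDesynchronized:
    def test_synchronized_limit(self, p_sync):
        rng = np.random.default_rng(4)
        hist = rng.uniform(-1, 1, (2, p_sync.n_active))
        u = 0.7
        np.testing.assert_array_equal(
            step_desynchronized(hist, u, p_sync),
            step_synchronized(hist[0], u, p_sync),
        )

    def test_memoryless_limit(self):
        p = RCParams(alpha=0.0, input_scale_mm=1.0)
        rng = np.random.default_rng(5)
        hist = rng.uniform(-1, 1, (2, p.n_active))
        np.testing.assert_array_equal(
            step_desynchronized(hist, 0.3, p),
            step_synchronized(np.zeros(p.n_active), 0.3, p),
        )

    def test_feedback_routing(self, p_unit):
        # node i >= k_N reads node i-k_N of step n-1; others reach into n-2
        k_n, n_act = p_unit.k_n, p_unit.n_active
        x1 = np.arange(n_act, dtype=float) / n_act
        x2 = -np.arange(n_act, dtype=float) / n_act
        out = step_desynchronized(np.vstack([x1, x2]), 0.0, p_unit,
                                  mask=np.zeros(n_act))
        expected_fb = np.concatenate([x2[n_act - k_n:], x1[: n_act - k_n]])
        np.testing.assert_allclose(out, np.sin(p_unit.alpha * expected_fb + p_unit.phi))


class TestRunReservoir:
    def test_bit_identical_to_slot_stream_oracle(self, p_default):
        rng = np.random.default_rng(0)
        u = rng.uniform(0.0, 30.0, 120)
        np.testing.assert_array_equal(
            run_reservoir(u, p_default), slot_stream_oracle(u, p_default)
        )

    def test_constant_input_reaches_fixed_point(self, p_default):
        states = run_reservoir(np.full(500, 8.0), p_default)
        assert np.max(np.abs(states[:, -1] - states[:, -2])) < 1e-9

    def test_single_sample_is_one_step_from_zero(self, p_unit):
        u0 = 0.4
        states = run_reservoir(np.array([u0]), p_unit)
        expected = step_desynchronized(np.zeros((2, p_unit.n_active)), u0, p_unit)
        np.testing.assert_array_equal(states[:, 0], expected)

    def test_zero_input_zero_phi_is_all_zero(self):
        p = RCParams(phi=0.0)
        states = run_reservoir(np.zeros(50), p)
        np.testing.assert_array_equal(states, np.zeros_like(states))

    def test_empty_input_rejected(self, p_default):
        with pytest.raises(InvalidParameterError):
            run_reservoir(np.array([]), p_default)

    def test_deterministic(self, p_default):
        u = np.random.default_rng(9).uniform(0, 20, 64)
        np.testing.assert_array_equal(
            run_reservoir(u, p_default), run_reservoir(u, p_default)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(-100, 100), min_size=1, max_size=40),
        alpha=st.floats(0.0, 0.99),
        seed=st.integers(0, 1000),
    )
    def test_states_always_within_sine_range(self, data, alpha, seed):
        p = RCParams(alpha=alpha, mask_seed=seed)
        states = run_reservoir(np.array(data), p)
        assert np.all(states >= -1.0) and np.all(states <= 1.0)

    def test_fading_memory_from_distinct_initial_states(self, p_default):
        u = np.random.default_rng(3).uniform(0, 20, 200)
        a = run_reservoir(u, p_default, init=np.full(p_default.n_active, 0.9))
        b = run_reservoir(u, p_default, init=np.full(p_default.n_active, -0.9))
        assert np.max(np.abs(a[:, -1] - b[:, -1])) < 1e-6


class TestWindowedStates:
    def test_matches_per_index_oracle(self, p_default):
        trace = np.random.default_rng(8).uniform(0, 25, 60)
        k_w = 15
        S = windowed_states(trace, p_default, k_w)
        for j in (15, 30, 60):
            np.testing.assert_array_equal(
                S[:, j - k_w], state_for_index(trace, j, p_default, k_w)
            )


class TestSpikeTrain:
    def test_no_feedback_means_single_echo(self):
        p = RCParams(alpha=0.0, input_scale_mm=1.0)
        echoes = spike_train_response(p, 0.1, 5)
        assert echoes[0] > 0
        np.testing.assert_allclose(echoes[1:], 0.0, atol=1e-15)

    def test_linearized_ratio_equals_alpha(self):
        p = RCParams(alpha=0.5, phi=0.0, input_scale_mm=1.0)
        echoes = spike_train_response(p, 1e-4, 6)
        ratios = echoes[1:] / echoes[:-1]
        np.testing.assert_allclose(ratios, 0.5, rtol=0.05)

    def test_default_params_strictly_decreasing(self, p_default):
        echoes = spike_train_response(p_default, 0.1, 8)
        assert np.all(np.diff(echoes) < 0)

    def test_requires_two_echoes(self, p_default):
        with pytest.raises(InvalidParameterError):
            spike_train_response(p_default, 0.1, 1)

    def test_quiescent_state_is_fixed_point(self, p_default):
        x = quiescent_state(p_default)
        assert abs(np.sin(p_default.alpha * x + p_default.phi) - x) < 1e-12


class TestParams:
    def test_derived_node_counts(self, p_default):
        assert (p_default.n_nodes, p_default.n_active, p_default.k_n) == (14, 12, 2)

    def test_non_integral_ratio_rejected(self):
        with pytest.raises(InvalidParameterError):
            RCParams(tau_ns=27.0)  # 27/2 not integral

    def test_n_prime_cannot_exceed_n(self):
        with pytest.raises(InvalidParameterError):
            RCParams(tau_prime_ns=30.0)

    def test_yaml_round_trip(self, p_default):
        assert RCParams.from_yaml(p_default.to_yaml()) == p_default

    def test_mask_reproducible_from_params(self, p_default):
        np.testing.assert_array_equal(p_default.mask(), p_default.mask())
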