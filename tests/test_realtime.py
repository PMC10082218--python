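"""Dual-sliding-window streaming predictor: indexing, causality, accuracy."""

import numpy as np
import pytest

from respirc import (
    RCParams,
    SessionTooShortError,
    StreamState,
    WindowConfig,
    WindowUnderflowError,
    build_training_batch,
    ingest,
    nmse,
    run_reservoir,
    run_session,
    state_for_index,
)
from respirc.errors import InvalidParameterError


class TestStateForIndex:
    def test_base_case_single_sample_window(self, p_default):
        trace = np.array([3.0, 7.0, 1.0])
        got = state_for_index(trace, 2, p_default, k_w=1)
        np.testing.assert_array_equal(got, run_reservoir([7.0], p_default)[:, -1])

    def test_constant_trace_shift_invariant(self, p_default):
        trace = np.full(100, 12.0)
        a = state_for_index(trace, 20, p_default, 15)
        b = state_for_index(trace, 77, p_default, 15)
        np.testing.assert_array_equal(a, b)

    def test_equals_final_column_of_window_run(self, p_default):
        trace = np.random.default_rng(0).uniform(0, 20, 50)
        j, k_w = 33, 15
        expected = run_reservoir(trace[j - k_w : j], p_default)[:, -1]
        np.testing.assert_array_equal(
            state_for_index(trace, j, p_default, k_w), expected
        )

    def test_underflow_raises(self, p_default):
        with pytest.raises(WindowUnderflowError):
            state_for_index(np.zeros(30), 10, p_default, 15)


class TestBuildTrainingBatch:
    def test_default_batch_has_576_columns(self, p_default):
        cfg = WindowConfig()  # k_tr=600, k_w=15, h_p=10
        window = np.random.default_rng(1).uniform(0, 20, 600)
        batch = build_training_batch(window, p_default, cfg)
        assert batch.n_samples == 576 == cfg.n_train_columns

    def test_tiny_window_enumeration(self, p_default):
        cfg = WindowConfig(k_tr=3, k_w=1, h_p=1)
        batch = build_training_batch(np.array([1.0, 2.0, 3.0]), p_default, cfg)
        assert batch.n_samples == 2
        # targets are the positions h_p ahead of each admissible index
        np.testing.assert_array_equal(batch.y, [2.0, 3.0])

    def test_constant_window_gives_identical_columns(self, p_default):
        cfg = WindowConfig()
        batch = build_training_batch(np.full(600, 9.0), p_default, cfg)
        assert np.all(batch.X == batch.X[:, :1])

    def test_wrong_length_window_signals_not_ready(self, p_default):
        with pytest.raises(InvalidParameterError, match="not ready"):
            build_training_batch(np.zeros(599), p_default, WindowConfig())


class TestIngest:
    def test_first_emission_targets_610(self, p_default):
        cfg = WindowConfig()
        stream = StreamState(p_default, cfg)
        trace = 10 + 5 * np.sin(np.arange(601) / 10.0)
        for y in trace[:600]:
            ingest(stream, float(y))
        assert stream.emissions[0][0] == 610
        # after ingesting sample 601 the next emission targets 611
        ingest(stream, float(trace[600]))
        assert stream.emissions[-1][0] == 611

    def test_training_window_after_601_is_samples_2_to_601(self, p_default):
        """The retrain at n=601 must use only samples 2..601: sample 1 is
        forgotten, so perturbing it must not change the emitted value."""
        cfg = WindowConfig()
        rng = np.random.default_rng(2)
        trace = 10 + 5 * np.sin(np.arange(601) / 9.0) + rng.normal(0, 0.1, 601)
        streams = (StreamState(p_default, cfg), StreamState(p_default, cfg))
        for s, first in zip(streams, (trace[0], trace[0] + 50.0)):
            s.ingest(float(first))
            for y in trace[1:]:
                s.ingest(float(y))
        a, b = streams
        assert a.emissions[-1][0] == b.emissions[-1][0] == 611
        assert a.emissions[-1][1] == b.emissions[-1][1]
        # while the stale sample was still inside the window it did matter
        assert a.emissions[0][1] != b.emissions[0][1]

    def test_constant_stream_predicts_constant(self, p_default):
        cfg = WindowConfig()
        stream = StreamState(p_default, cfg)
        for _ in range(620):
            stream.ingest(10.0)
        preds = [yhat for _, yhat in stream.emissions]
        np.testing.assert_allclose(preds, 10.0, rtol=0.01)

    def test_non_finite_sample_rejected(self, p_default):
        stream = StreamState(p_default, WindowConfig())
        stream.ingest(1.0)
        assert stream.ingest(float("nan")) is None
        assert stream.n == 1  # state unchanged


class TestRunSession:
    def test_record_count_and_alignment(self, p_default, sine_trace):
        cfg = WindowConfig()
        records = run_session(sine_trace, p_default, cfg)
        assert len(records) == len(sine_trace) - cfg.k_tr - cfg.h_p + 1 == 2991
        assert records[0].index == 610
        assert records[-1].index == 3600
        # ground truth column matches the trace at each target index
        for r in records[:5] + records[-5:]:
            assert r.y == sine_trace[r.index - 1]
            assert r.ae == abs(r.y - r.yhat)

    def test_boundary_trace_yields_one_record(self, p_default):
        cfg = WindowConfig(k_tr=40, k_w=5, h_p=3)
        trace = np.random.default_rng(3).uniform(0, 20, 43)
        records = run_session(trace, p_default, cfg)
        assert len(records) == 1
        assert records[0].index == 43

    def test_too_short_trace_raises(self, p_default):
        with pytest.raises(SessionTooShortError):
            run_session(np.zeros(100), p_default, WindowConfig())

    def test_sine_trace_is_predictable(self, p_default, sine_trace):
        records = run_session(sine_trace, p_default, WindowConfig())
        assert nmse(records) < 0.05

    def test_causality_future_samples_do_not_affect_emission(self, p_default):
        """The prediction emitted at step n must not change when samples
        after n are perturbed."""
        cfg = WindowConfig(k_tr=60, k_w=5, h_p=4)
        rng = np.random.default_rng(4)
        trace = 10 + 5 * np.sin(np.arange(80) / 6.0) + rng.normal(0, 0.2, 80)
        perturbed = trace.copy()
        perturbed[70:] += 100.0  # only samples after n=70
        a, b = StreamState(p_default, cfg), StreamState(p_default, cfg)
        for y in trace:
            a.ingest(float(y))
        for y in perturbed:
            b.ingest(float(y))
        emit_a = dict(a.emissions)
        emit_b = dict(b.emissions)
        # all emissions made at steps n <= 70 agree exactly
        for target in range(cfg.k_tr + cfg.h_p, 70 + cfg.h_p + 1):
            assert emit_a[target] == emit_b[target]

    def test_windowed_and_continuous_modes_both_run(self, p_default):
        t = np.arange(900) / 30.0
        trace = 10 + 6 * np.sin(2 * np.pi * 0.25 * t)
        cfg = WindowConfig()
        rec_w = run_session(trace, p_default, cfg, mode="windowed")
        rec_c = run_session(trace, p_default, cfg, mode="continuous")
        assert len(rec_w) == len(rec_c)
        assert nmse(rec_w) < 0.05 and nmse(rec_c) < 0.5

    def test_deterministic_replay(self, p_default, sine_trace):
        cfg = WindowConfig()
        a = run_session(sine_trace[:800], p_default, cfg)
        b = run_session(sine_trace[:800], p_default, cfg)
        assert [(r.index, r.yhat) for r in a] == [(r.index, r.yhat) for r in b]


class TestWindowConfig:
    def test_look_ahead_time(self):
        assert WindowConfig(h_p=10).t_p_ms == pytest.approx(333.3, abs=0.1)
        assert WindowConfig(h_p=2).t_p_ms == pytest.approx(66.7, abs=0.1)

    def test_cross_field_constraint_enforced(self):
        with pytest.raises(InvalidParameterError, match="k_tr > k_w"):
            WindowConfig(k_tr=20, k_w=15, h_p=10)


def test_sparser_retraining_reuses_weights(p_default):
    """retrain_every=M keeps the last solved weights for M-1 steps; on a
    stationary trace the predictions stay close to the per-sample path."""
    cfg = WindowConfig(k_tr=60, k_w=5, h_p=3)
    t = np.arange(120) / 30.0
    trace = 10 + 5 * np.sin(2 * np.pi * 0.3 * t)
    dense = StreamState(p_default, cfg, retrain_every=1)
    sparse = StreamState(p_default, cfg, retrain_every=5)
    for y in trace:
        dense.ingest(float(y))
        sparse.ingest(float(y))
    d, s = dict(dense.emissions), dict(sparse.emissions)
    assert set(d) == set(s)
    # identical at retrain steps, merely close in between
    assert d[cfg.k_tr + cfg.h_p] == s[cfg.k_tr + cfg.h_p]
    np.testing.assert_allclose(list(s.values()), list(d.values()), atol=1.0)
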