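"""Dual-sliding-window streaming predictor.

Two windows advance in lock-step over the incoming position stream: a
training window of the latest ``k_tr`` samples, from which the readout
weights are re-solved on every new sample, and an input window of the
latest ``k_w`` samples, which is driven through a zero-initialized
reservoir to produce the feature vector for the prediction ``h_p``
samples ahead.  With the defaults (k_tr=600, k_w=15, h_p=10 at 30 Hz)
the first training window is {y_1..y_600} and the first emitted
prediction targets sample 610; after sample 601 arrives the window is
{y_2..y_601} and the emission targets 611, and so on until the session
ends.

Indices at the interface are 1-based, matching the clinical log
convention (the first recorded position is y_1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidParameterError,
    SessionTooShortError,
    ShapeError,
    WindowUnderflowError,
)
from .params import RCParams, WindowConfig
from .readout import ReadoutWeights, TrainingBatch, predict, train_ridge
from .reservoir import run_reservoir, windowed_states

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionRecord",
    "StreamState",
    "state_for_index",
    "build_training_batch",
    "ingest",
    "run_session",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One aligned (target index, ground truth, prediction) triple.

    ``index`` is the 1-based sample index of the predicted position;
    ``ae = |y - yhat|`` is the absolute error in mm.
    """

    index: int
    y: float
    yhat: float

    @property
    def ae(self) -> float:
        return abs(self.y - self.yhat)


def state_for_index(
    trace: np.ndarray, j: int, p: RCParams, k_w: int
) -> np.ndarray:
    """Reservoir state from the k_w-sample input window ending at index j.

    A zero-initialized reservoir is driven with samples j-k_w+1 .. j
    (1-based) and the final state returned.  Equals column k_w of
    :func:`respirc.reservoir.run_reservoir` on that window.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if j < k_w:
        raise WindowUnderflowError(
            f"index {j} has no full input window of k_w={k_w} samples behind it"
        )
    if j > trace.size:
        raise WindowUnderflowError(f"index {j} beyond trace of length {trace.size}")
    window = trace[j - k_w : j]
    return run_reservoir(window, p)[:, -1]


def build_training_batch(
    window: np.ndarray, p: RCParams, cfg: WindowConfig
) -> TrainingBatch:
    """Training pairs (state at j, position at j+h_p) over one k_tr window.

    ``window`` holds exactly k_tr consecutive samples.  Admissible
    within-window indices j need a full k_w input window behind them and
    an observed target h_p ahead of them, giving k_tr - h_p - k_w + 1
    columns (576 at the defaults).
    """
    window = np.asarray(window, dtype=float).ravel()
    if window.size != cfg.k_tr:
        raise InvalidParameterError(
            f"training window must hold exactly k_tr={cfg.k_tr} samples, "
            f"got {window.size} (stream not ready)"
        )
    n_cols = cfg.n_train_columns
    states = windowed_states(window, p, cfg.k_w)[:, :n_cols]
    targets = window[cfg.k_w + cfg.h_p - 1 : cfg.k_w + cfg.h_p - 1 + n_cols]
    return TrainingBatch(X=states, y=targets)


class StreamState:
    """Streaming state: sample/state history, counter, current weights.

    Feed samples with :meth:`ingest`; once ``k_tr`` samples are held every
    further sample retrains the readout on the current training window and
    emits a prediction for index ``n + h_p``.  The emitted prediction is
    resolved into a :class:`PredictionRecord` when its target sample
    arrives.
    """

    def __init__(
        self,
        p: RCParams,
        cfg: WindowConfig,
        bias: bool = False,
        retrain_every: int = 1,
    ):
        if retrain_every < 1:
            raise InvalidParameterError("retrain_every must be >= 1")
        self.p = p
        self.cfg = cfg
        self.bias = bias
        self.retrain_every = retrain_every  # M > 1 trades accuracy for speed
        self.n = 0  # 1-based index of the latest ingested sample
        self.weights: ReadoutWeights | None = None
        self.emissions: list[tuple[int, float]] = []  # (target index, yhat)
        self._pending: dict[int, float] = {}
        self._mask = p.mask()
        cap = max(4 * cfg.k_tr, 4096)
        self._y = np.empty(cap)
        self._S = np.empty((p.n_active, cap))  # column j-k_w holds state(j)
        self._n_states = 0

    # -- internal buffers -------------------------------------------------

    def _grow(self) -> None:
        if self.n >= self._y.size:
            self._y = np.concatenate([self._y, np.empty(self._y.size)])
        if self._n_states >= self._S.shape[1]:
            self._S = np.concatenate([self._S, np.empty(self._S.shape)], axis=1)

    def _append_state(self) -> None:
        """Compute state(n) from the latest k_w samples once available."""
        k_w = self.cfg.k_w
        if self.n < k_w:
            return
        window = self._y[self.n - k_w : self.n]
        state = run_reservoir(window, self.p)[:, -1]
        self._S[:, self._n_states] = state
        self._n_states += 1

    def _state_at(self, j: int) -> np.ndarray:
        return self._S[:, j - self.cfg.k_w]

    def _retrain(self) -> None:
        cfg = self.cfg
        n = self.n
        j0, j1 = n - cfg.k_tr + cfg.k_w, n - cfg.h_p
        X = self._S[:, j0 - cfg.k_w : j1 - cfg.k_w + 1]
        y_t = self._y[j0 + cfg.h_p - 1 : j1 + cfg.h_p]
        batch = TrainingBatch(X=X, y=y_t)
        self.weights = train_ridge(batch, self.p.lambda_reg, bias=self.bias)

    # -- streaming API ----------------------------------------------------

    def ingest(self, y_n: float) -> PredictionRecord | None:
        """Ingest one sample; return the resolved record for it, if any.

        Retrains and emits a new prediction (logged in :attr:`emissions`)
        whenever at least ``k_tr`` samples are held.  Non-finite samples
        are rejected with a logged warning and leave the state unchanged.
        """
        if not math.isfinite(y_n):
            logger.warning("rejected non-finite sample %r at position %d", y_n, self.n + 1)
            return None
        self.n += 1
        self._grow()
        self._y[self.n - 1] = y_n
        self._append_state()

        record = None
        if self.n in self._pending:
            record = PredictionRecord(self.n, y_n, self._pending.pop(self.n))

        if self.n >= self.cfg.k_tr:
            if self.weights is None or (self.n - self.cfg.k_tr) % self.retrain_every == 0:
                self._retrain()
            yhat = predict(self.weights, self._state_at(self.n))
            target = self.n + self.cfg.h_p
            self.emissions.append((target, yhat))
            self._pending[target] = yhat
            logger.debug("retrained at n=%d, emitted yhat for index %d", self.n, target)
        return record


def ingest(stream: StreamState, y_n: float) -> PredictionRecord | None:
    """Functional alias for :meth:`StreamState.ingest`."""
    return stream.ingest(y_n)


def run_session(
    trace: np.ndarray,
    p: RCParams,
    cfg: WindowConfig | None = None,
    bias: bool = False,
    mode: str = "windowed",
) -> list[PredictionRecord]:
    """Replay a full trace through the streaming predictor.

    Returns one record per predicted index with observed ground truth:
    len(trace) - k_tr - h_p + 1 records, targets k_tr + h_p .. len(trace).

    ``mode='windowed'`` (default) re-drives a fresh reservoir over each
    k_w input window, the reading under which k_w is meaningful;
    ``mode='continuous'`` instead takes features from one reservoir run
    continuously over the whole trace (provided for comparison).
    """
    cfg = cfg or WindowConfig()
    trace = np.asarray(trace, dtype=float).ravel()
    min_len = cfg.k_tr + cfg.h_p
    if trace.size < min_len:
        raise SessionTooShortError(
            f"trace of {trace.size} samples cannot support a session: need at "
            f"least k_tr + h_p = {min_len}"
        )
    if mode == "windowed":
        stream = StreamState(p, cfg, bias=bias)
        records = []
        for y_n in trace:
            rec = stream.ingest(float(y_n))
            if rec is not None:
                records.append(rec)
        return records
    if mode == "continuous":
        return _run_session_continuous(trace, p, cfg, bias)
    raise InvalidParameterError(f"unknown mode {mode!r}; use 'windowed' or 'continuous'")


def _run_session_continuous(
    trace: np.ndarray, p: RCParams, cfg: WindowConfig, bias: bool
) -> list[PredictionRecord]:
    """Sliding retrain over features from one continuously-running reservoir."""
    T = trace.size
    S = run_reservoir(trace, p)  # column n-1 is state(n), full history
    records = []
    for n in range(cfg.k_tr, T - cfg.h_p + 1):
        j0, j1 = n - cfg.k_tr + cfg.k_w, n - cfg.h_p
        X = S[:, j0 - 1 : j1]
        y_t = trace[j0 + cfg.h_p - 1 : j1 + cfg.h_p]
        w = train_ridge(TrainingBatch(X=X, y=y_t), p.lambda_reg, bias=bias)
        yhat = predict(w, S[:, n - 1])
        records.append(PredictionRecord(n + cfg.h_p, float(trace[n + cfg.h_p - 1]), yhat))
    return records
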