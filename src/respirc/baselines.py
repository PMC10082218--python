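"""Comparison predictors: fixed-model RC and the reservoir-less ridge regressor.

``run_fixed_model`` trains the readout once on the first training window
and never retrains — the conventional train/test split whose weights go
stale when the breathing pattern drifts mid-session.  ``run_ridge_only``
keeps the dual-sliding-window retraining protocol but feeds the readout
the raw last-``k_w`` samples (default k_w = 1) instead of reservoir
states, isolating the contribution of the reservoir itself.  Both emit
the same :class:`~respirc.realtime.PredictionRecord` stream as the
real-time predictor, so all metrics and reports are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, SessionTooShortError
from .params import RCParams, WindowConfig
from .readout import TrainingBatch, predict, train_ridge
from .realtime import PredictionRecord, build_training_batch
from .reservoir import windowed_states

logger = logging.getLogger(__name__)

__all__ = ["BaselineConfig", "run_fixed_model", "run_ridge_only", "raw_feature_matrix"]


@dataclass(frozen=True)
class BaselineConfig:
    """Baseline selection: mode, fixed-model training length, ridge-only window.

    ``t_tr_s`` (20 or 60 s) maps to k_tr = t_tr * sample rate for the
    fixed-model RC; ``k_w`` defaults to 1 for the ridge-only regressor,
    which includes a bias (intercept) feature unless ``bias`` is False.
    """

    mode: str = "fixed_rc"
    t_tr_s: float = 20.0
    k_w: int = 1
    bias: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_rc", "ridge_only"):
            raise InvalidParameterError(
                f"mode must be 'fixed_rc' or 'ridge_only', got {self.mode!r}"
            )
        if self.t_tr_s <= 0:
            raise InvalidParameterError("t_tr_s must be > 0")
        if self.k_w < 1:
            raise InvalidParameterError("k_w must be >= 1")

    def k_tr(self, sample_rate_hz: float = 30.0) -> int:
        return round(self.t_tr_s * sample_rate_hz)


def run_fixed_model(
    trace: np.ndarray,
    p: RCParams,
    cfg: WindowConfig | None = None,
) -> list[PredictionRecord]:
    """Train W_out once on the first k_tr samples, then predict without retraining.

    Prediction features are identical to the real-time predictor's
    (fresh-reservoir drive over the k_w window ending at each index), so
    any performance gap is attributable to the frozen weights alone.
    Raises :class:`SessionTooShortError` when the trace cannot cover the
    training window plus one look-ahead (the caller may exclude such
    traces with a logged reason).
    """
    cfg = cfg or WindowConfig()
    trace = np.asarray(trace, dtype=float).ravel()
    min_len = cfg.k_tr + cfg.h_p
    if trace.size < min_len:
        logger.warning(
            "trace of %d samples excluded from fixed-model run: needs >= %d",
            trace.size, min_len,
        )
        raise SessionTooShortError(
            f"trace of {trace.size} samples shorter than k_tr + h_p = {min_len}"
        )
    batch = build_training_batch(trace[: cfg.k_tr], p, cfg)
    weights = train_ridge(batch, p.lambda_reg)
    # state for every index j >= k_w, column c <-> j = k_w + c (1-based)
    S = windowed_states(trace, p, cfg.k_w)
    records = []
    for n in range(cfg.k_tr, trace.size - cfg.h_p + 1):
        yhat = predict(weights, S[:, n - cfg.k_w])
        target = n + cfg.h_p
        records.append(PredictionRecord(target, float(trace[target - 1]), yhat))
    return records


def raw_feature_matrix(trace: np.ndarray, k_w: int) -> np.ndarray:
    """Raw sliding-window feature matrix: column c is trace[c .. c+k_w-1].

    Column c corresponds to 1-based index j = k_w + c; this is exactly the
    feature matrix the ridge-only baseline regresses on (the reservoir
    state matrix is replaced by the input samples themselves).
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < k_w:
        raise InvalidParameterError("trace shorter than k_w")
    return np.lib.stride_tricks.sliding_window_view(trace, k_w).T.copy()


def run_ridge_only(
    trace: np.ndarray,
    cfg: WindowConfig | None = None,
    bcfg: BaselineConfig | None = None,
    lambda_reg: float = 0.01,
) -> list[PredictionRecord]:
    """Dual-sliding-window ridge regression directly on raw samples.

    Identical retraining protocol to the real-time RC — the training
    window of the latest k_tr samples slides with every new sample and
    the weights are re-solved — but the features are the raw ``k_w``
    input samples (default 1) plus a bias, with no reservoir in between.
    """
    bcfg = bcfg or BaselineConfig(mode="ridge_only")
    cfg = cfg or WindowConfig()
    k_w = bcfg.k_w
    trace = np.asarray(trace, dtype=float).ravel()
    min_len = cfg.k_tr + cfg.h_p
    if trace.size < min_len:
        raise SessionTooShortError(
            f"trace of {trace.size} samples shorter than k_tr + h_p = {min_len}"
        )
    if cfg.k_tr <= k_w + cfg.h_p:
        raise InvalidParameterError("k_tr must exceed k_w + h_p")
    F = raw_feature_matrix(trace, k_w)  # column c <-> j = k_w + c
    records = []
    for n in range(cfg.k_tr, trace.size - cfg.h_p + 1):
        j0, j1 = n - cfg.k_tr + k_w, n - cfg.h_p
        X = F[:, j0 - k_w : j1 - k_w + 1]
        y_t = trace[j0 + cfg.h_p - 1 : j1 + cfg.h_p]
        w = train_ridge(TrainingBatch(X=X, y=y_t), lambda_reg, bias=bcfg.bias)
        yhat = predict(w, F[:, n - k_w])
        target = n + cfg.h_p
        records.append(PredictionRecord(target, float(trace[target - 1]), yhat))
    return records
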