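"""Prediction-quality metrics: NMSE, MAE, RMSE, AE series and TBE.

NMSE normalizes the squared prediction error by the squared deviation of
the ground truth from its mean over the evaluated span, so the trivial
mean predictor scores exactly 1.  MAE and RMSE are in mm.  Therapeutic
beam efficiency (TBE) is the percentage of predicted time points whose
absolute error stays below a clinical margin (1, 3 or 5 mm): the fraction
of a radiotherapy session during which the beam could stay on-target.

All metrics are computed over every emitted prediction of a session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError, MetricUndefinedError
from .realtime import PredictionRecord

__all__ = ["nmse", "mae", "rmse", "tbe", "MetricsReport", "compute_report"]

TBE_THRESHOLDS_MM = (1.0, 3.0, 5.0)


def _arrays(records: Sequence[PredictionRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise MetricUndefinedError("no prediction records to evaluate")
    y = np.array([r.y for r in records])
    yhat = np.array([r.yhat for r in records])
    return y, yhat


def nmse(records: Sequence[PredictionRecord]) -> float:
    """Normalized mean square error: sum (yhat-y)^2 / sum (ybar-y)^2."""
    y, yhat = _arrays(records)
    if y.size < 2:
        raise MetricUndefinedError("NMSE needs at least 2 records")
    denom = float(np.sum((y.mean() - y) ** 2))
    if denom == 0.0:
        raise MetricUndefinedError(
            "NMSE undefined: ground truth has zero variance over the evaluated span"
        )
    return float(np.sum((yhat - y) ** 2) / denom)


def mae(records: Sequence[PredictionRecord]) -> float:
    """Mean absolute error, mm."""
    y, yhat = _arrays(records)
    return float(np.mean(np.abs(yhat - y)))


def rmse(records: Sequence[PredictionRecord]) -> float:
    """Root mean square error, mm."""
    y, yhat = _arrays(records)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def tbe(records: Sequence[PredictionRecord], threshold_mm: float) -> float:
    """Therapeutic beam efficiency: 100 * fraction of records with AE < threshold."""
    if threshold_mm <= 0:
        raise InvalidParameterError(f"threshold must be > 0 mm, got {threshold_mm}")
    y, yhat = _arrays(records)
    return float(100.0 * np.mean(np.abs(yhat - y) < threshold_mm))


@dataclass(frozen=True)
class MetricsReport:
    """Session-level summary: NMSE, MAE/RMSE (mm), TBE at 1/3/5 mm (%)."""

    nmse: float
    mae: float
    rmse: float
    tbe_1mm: float
    tbe_3mm: float
    tbe_5mm: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "nmse": self.nmse,
            "mae_mm": self.mae,
            "rmse_mm": self.rmse,
            "tbe_1mm_pct": self.tbe_1mm,
            "tbe_3mm_pct": self.tbe_3mm,
            "tbe_5mm_pct": self.tbe_5mm,
            "n_points": self.n_points,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        lines = [f"{k.ljust(width)}  {v:.4f}" if isinstance(v, float) else
                 f"{k.ljust(width)}  {v}" for k, v in d.items()]
        return "\n".join(lines)


def compute_report(records: Sequence[PredictionRecord]) -> MetricsReport:
    """All session metrics over every emitted prediction."""
    return MetricsReport(
        nmse=nmse(records),
        mae=mae(records),
        rmse=rmse(records),
        tbe_1mm=tbe(records, 1.0),
        tbe_3mm=tbe(records, 3.0),
        tbe_5mm=tbe(records, 5.0),
        n_points=len(records),
    )
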