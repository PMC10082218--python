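"""Linear readout trained by ridge regression.

The reservoir is fixed; only the output weights are learned.  Given the
state matrix X (N' rows, one column per training sample) and the target
row Y, the readout solves

    W_out = Y X^T (X X^T + lambda I)^{-1}

via a symmetric linear solve (never an explicit inverse), and predicts
with the dot product yhat(n) = W_out . x(n).  ``lambda_reg`` defaults to
0.01; an optional bias appends a constant-1 row to X, off by default so
the readout operates directly on raw (possibly non-zero-mean) states.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ShapeError, SingularSystemError

__all__ = ["TrainingBatch", "ReadoutWeights", "train_ridge", "predict"]


@dataclass(frozen=True)
class TrainingBatch:
    """Design matrix X (features x samples) and target row y (one per column)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2:
            raise ShapeError(f"X must be 2-D (features x samples), got ndim={X.ndim}")
        if y.size != X.shape[1]:
            raise ShapeError(
                f"target length {y.size} != number of state columns {X.shape[1]}"
            )
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ShapeError("training batch contains non-finite values")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ReadoutWeights:
    """Trained output weights W_out (plus optional bias weight)."""

    w: np.ndarray
    lambda_reg: float
    n_train: int
    bias: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float).ravel()
        if not np.isfinite(w).all():
            raise ShapeError("readout weights contain non-finite values")
        object.__setattr__(self, "w", w)

    @property
    def n_states(self) -> int:
        """State dimension the weights apply to (excluding the bias slot)."""
        return self.w.size - (1 if self.bias else 0)

    def to_json(self, config_hash: str | None = None) -> str:
        return json.dumps(
            {
                "w": self.w.tolist(),
                "lambda_reg": self.lambda_reg,
                "n_train": self.n_train,
                "bias": self.bias,
                "rc_config_hash": config_hash,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReadoutWeights":
        d = json.loads(text)
        return cls(
            w=np.asarray(d["w"], dtype=float),
            lambda_reg=d["lambda_reg"],
            n_train=d["n_train"],
            bias=d["bias"],
        )


def train_ridge(
    batch: TrainingBatch, lambda_reg: float = 0.01, bias: bool = False
) -> ReadoutWeights:
    """Solve W_out = Y X^T (X X^T + lambda I)^{-1} for the readout weights.

    The normal equations are solved as a symmetric linear system.  With
    ``lambda_reg = 0`` a rank-deficient Gram matrix raises
    :class:`SingularSystemError` with guidance to set lambda_reg > 0.
    Fewer training columns than features triggers a warning (the solve is
    still regularized) rather than a failure.
    """
    X, y = batch.X, batch.y
    if bias:
        X = np.vstack([X, np.ones(X.shape[1])])
    n_feat = X.shape[0]
    if batch.n_samples < n_feat:
        warnings.warn(
            f"only {batch.n_samples} training columns for {n_feat} features; "
            "the ridge solve is underdetermined",
            stacklevel=2,
        )
    gram = X @ X.T + lambda_reg * np.eye(n_feat)
    rhs = X @ y
    try:
        w = scipy.linalg.solve(gram, rhs, assume_a="sym")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise SingularSystemError(
            "ridge normal equations are singular; set lambda_reg > 0 "
            "(default 0.01) to regularize the solve"
        ) from exc
    if not np.isfinite(w).all():
        raise SingularSystemError(
            "ridge solve produced non-finite weights; set lambda_reg > 0 "
            "(default 0.01) to regularize the solve"
        )
    return ReadoutWeights(w=w, lambda_reg=lambda_reg, n_train=batch.n_samples, bias=bias)


def predict(weights: ReadoutWeights, x: np.ndarray) -> float:
    """Readout prediction yhat = W_out . x (plus bias weight if enabled)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != weights.n_states:
        raise ShapeError(
            f"state vector length {x.size} != readout dimension {weights.n_states}"
        )
    if weights.bias:
        return float(weights.w[:-1] @ x + weights.w[-1])
    return float(weights.w @ x)
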