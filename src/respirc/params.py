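"""Reservoir hyperparameters and the input mask.

A time-multiplexed delay-line reservoir is fully specified by the feedback
gain ``alpha``, input gain ``beta``, nonlinearity bias phase ``phi``, the
virtual-node separation ``theta`` (ns), the loop round-trip delay ``tau``
(ns) and the input hold time ``tau_prime`` (ns).  The loop capacity is
``N = tau/theta`` virtual nodes of which ``N' = tau_prime/theta`` are
actively driven; the mismatch ``k_N = N - N'`` desynchronizes the node
interactions (``k_N = 0`` is the classical synchronized delay reservoir).

Defaults reproduce the bench configuration this simulator models:
``alpha=0.87``, ``beta=2.29``, ``phi=0.55*pi``, ``theta=2`` ns,
``tau=28`` ns, ``tau_prime=24`` ns (so ``N=14``, ``N'=12``, ``k_N=2``)
and ridge regularization ``lambda_reg=0.01``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
import yaml

from .errors import InvalidParameterError

MaskKind = Literal["binary", "uniform"]

_INT_TOL = 1e-9


def _as_int_ratio(num: float, den: float, what: str) -> int:
    """Validate that num/den is integral within 1e-9 and return it."""
    ratio = num / den
    n = round(ratio)
    if abs(ratio - n) > _INT_TOL:
        raise InvalidParameterError(
            f"{what} = {num}/{den} = {ratio} is not integral within {_INT_TOL}"
        )
    return int(n)


def make_mask(n_nodes: int, kind: MaskKind = "binary", seed: int = 0) -> np.ndarray:
    """Draw the piecewise input-mask levels ``m_i``, one per virtual node.

    The mask diversifies how a single held input sample drives each of the
    ``n_nodes`` time-multiplexed nodes.  ``kind='binary'`` draws levels from
    {-1, +1} (the delay-RC standard); ``kind='uniform'`` draws from
    U[-1, 1].  Deterministic for a fixed ``seed``.
    """
    if n_nodes < 1:
        raise InvalidParameterError(f"n_nodes must be >= 1, got {n_nodes}")
    rng = np.random.default_rng(seed)
    if kind == "binary":
        mask = rng.choice(np.array([-1.0, 1.0]), size=n_nodes)
    elif kind == "uniform":
        mask = rng.uniform(-1.0, 1.0, size=n_nodes)
    else:
        raise InvalidParameterError(
            f"unknown mask kind {kind!r}; valid kinds: 'binary', 'uniform'"
        )
    mask.flags.writeable = False
    return mask


@dataclass(frozen=True)
class RCParams:
    """All reservoir hyperparameters in one validated record.

    Attributes
    ----------
    alpha : float
        Feedback (loop) gain; ``|alpha| < 1`` gives fading memory.
    beta : float
        Input gain applied to the masked input.
    phi : float
        Bias phase of the sinusoidal nonlinearity, radians.
    theta_ns : float
        Virtual-node separation, ns.
    tau_ns : float
        Loop round-trip delay, ns.  ``N = tau/theta`` must be integral.
    tau_prime_ns : float
        Input hold time, ns.  ``N' = tau_prime/theta`` must be integral
        and ``N' <= N``.
    lambda_reg : float
        Ridge regularization for the readout solve.
    mask_seed : int
        Seed for the input mask draw.
    mask_kind : {"binary", "uniform"}
        Distribution of the mask levels.
    input_scale_mm : float
        Full-scale of the sensor-to-drive mapping: recorded positions are
        divided by this before entering the masked input product, emulating
        the DAC/modulator drive range that keeps the nonlinearity argument
        within a monotonic flank of its transfer function.  The default
        60 mm maps the largest clinically observed amplitude (30 mm) to a
        peak phase swing of about beta/2 radians.
    """

    alpha: float = 0.87
    beta: float = 2.29
    phi: float = 0.55 * math.pi
    theta_ns: float = 2.0
    tau_ns: float = 28.0
    tau_prime_ns: float = 24.0
    lambda_reg: float = 0.01
    mask_seed: int = 42
    mask_kind: MaskKind = "binary"
    input_scale_mm: float = 60.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InvalidParameterError(f"alpha must be >= 0, got {self.alpha}")
        if self.theta_ns <= 0:
            raise InvalidParameterError(f"theta must be > 0, got {self.theta_ns}")
        if self.tau_ns <= 0 or self.tau_prime_ns <= 0:
            raise InvalidParameterError("tau and tau_prime must be > 0")
        if self.input_scale_mm <= 0:
            raise InvalidParameterError(
                f"input_scale_mm must be > 0, got {self.input_scale_mm}"
            )
        if self.lambda_reg < 0:
            raise InvalidParameterError(
                f"lambda_reg must be >= 0, got {self.lambda_reg}"
            )
        n = _as_int_ratio(self.tau_ns, self.theta_ns, "N = tau/theta")
        n_prime = _as_int_ratio(
            self.tau_prime_ns, self.theta_ns, "N' = tau_prime/theta"
        )
        if n_prime > n:
            raise InvalidParameterError(
                f"N' = {n_prime} exceeds loop capacity N = {n}"
            )
        if n_prime < 1:
            raise InvalidParameterError("N' must be >= 1")

    @property
    def n_nodes(self) -> int:
        """Loop capacity N = round(tau/theta)."""
        return round(self.tau_ns / self.theta_ns)

    @property
    def n_active(self) -> int:
        """Active virtual nodes N' = round(tau_prime/theta)."""
        return round(self.tau_prime_ns / self.theta_ns)

    @property
    def k_n(self) -> int:
        """Desynchronization node mismatch k_N = N - N' (0 = synchronized)."""
        return self.n_nodes - self.n_active

    def mask(self) -> np.ndarray:
        """The length-N' input mask reproduced from ``mask_seed``."""
        return make_mask(self.n_active, self.mask_kind, self.mask_seed)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RCParams":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RCParams":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class WindowConfig:
    """Dual-sliding-window configuration for the streaming predictor.

    ``k_tr`` samples of training window (600 = 20 s at 30 Hz) and ``k_w``
    samples of input window slide in sync; each retrain predicts ``h_p``
    samples ahead (look-ahead time ``t_p = h_p * t_s``).
    """

    k_tr: int = 600
    k_w: int = 15
    h_p: int = 10
    t_s_ms: float = 100.0 / 3.0  # 33.3 ms <-> 30 Hz

    def __post_init__(self) -> None:
        for name in ("k_tr", "k_w", "h_p"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise InvalidParameterError(f"{name} must be a positive integer, got {v!r}")
        if self.t_s_ms <= 0:
            raise InvalidParameterError(f"t_s_ms must be > 0, got {self.t_s_ms}")
        if self.k_tr <= self.k_w + self.h_p:
            raise InvalidParameterError(
                f"constraint k_tr > k_w + h_p violated: "
                f"{self.k_tr} <= {self.k_w} + {self.h_p}"
            )

    @property
    def t_p_ms(self) -> float:
        """Look-ahead time t_p = h_p * t_s, ms."""
        return self.h_p * self.t_s_ms

    @property
    def n_train_columns(self) -> int:
        """Columns in one training batch: k_tr - h_p - k_w + 1 (576 at defaults)."""
        return self.k_tr - self.h_p - self.k_w + 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WindowConfig":
        return cls(**d)


def injection_time_us(k_tr: int, n_active: int, theta_ns: float) -> float:
    """Reservoir injection time k_tr * N' * theta for one training pass, µs.

    At the defaults (k_tr=600, N'=12, theta=2 ns) this is 14.4 µs.
    """
    return k_tr * n_active * theta_ns * 1e-3
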