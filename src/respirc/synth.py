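"""Synthetic respiratory-motion traces.

Patient breathing recorded by an external surrogate is quasi-sinusoidal —
a peak-valley-peak cycle with a flattened exhale plateau — but rarely
clean: amplitude and frequency drift, transient pulses (cough/sigh),
baseline shifts, double-breathe secondary peaks and outright shape
inversion are all observed at radiotherapy clinics.  This module
generates such traces so the prediction pipeline can be exercised without
patient data.

The clean waveform family is a raised cosine raised to a shape power p,

    y(t) = baseline + A * ((1 + cos(2*pi*f*t)) / 2)**p ,

which for p = 1 is a pure sinusoid and for p > 1 reproduces the
characteristic narrow inhale peak over a flat exhale plateau.  Cohort
ranges mirror clinical observation: 3-20 breaths per minute, amplitudes
5-30 mm, durations 1-4 min, sampled at 30 Hz.  Irregularities are
injected as deterministic transformations, sensor noise is additive
Gaussian, and every generator is reproducible from its seed.  The clean
(pre-noise) trace is retained alongside the noisy one so prediction error
can be separated from the noise floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage

from .errors import InvalidParameterError

__all__ = [
    "BreathingSpec",
    "MotionTrace",
    "generate_base",
    "generate",
    "inject_irregularity",
    "add_sensor_noise",
    "gaussian_filter",
    "generate_cohort",
    "IRREGULARITY_KINDS",
]

IRREGULARITY_KINDS = (
    "amplitude_drift",
    "frequency_drift",
    "pulse",
    "baseline_shift",
    "double_breathe",
    "inverse_shape",
)

BPM_RANGE = (3.0, 20.0)
AMPLITUDE_RANGE_MM = (5.0, 30.0)
DURATION_RANGE_S = (60.0, 240.0)


@dataclass(frozen=True)
class MotionTrace:
    """Uniformly sampled displacement series, mm.

    ``clean`` optionally carries the pre-noise ground truth of the same
    length.
    """

    positions: np.ndarray
    sample_rate_hz: float = 30.0
    clean: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).ravel()
        if pos.size == 0:
            raise InvalidParameterError("trace must be non-empty")
        if not np.isfinite(pos).all():
            raise InvalidParameterError("trace contains non-finite positions")
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample_rate_hz must be > 0")
        object.__setattr__(self, "positions", pos)
        if self.clean is not None:
            clean = np.asarray(self.clean, dtype=float).ravel()
            if clean.size != pos.size:
                raise InvalidParameterError("clean trace length mismatch")
            object.__setattr__(self, "clean", clean)

    def __len__(self) -> int:
        return self.positions.size

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.positions.size) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.positions.size / self.sample_rate_hz

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV (time_s, position_mm), plus clean_mm if kept."""
        cols = {"time_s": self.times_s, "position_mm": self.positions}
        if self.clean is not None:
            cols["clean_mm"] = self.clean
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MotionTrace":
        df = pd.read_csv(path)
        if "position_mm" not in df.columns or "time_s" not in df.columns:
            raise InvalidParameterError(
                f"{path}: expected columns time_s, position_mm"
            )
        t = df["time_s"].to_numpy()
        if t.size > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InvalidParameterError(f"{path}: sampling is not uniform")
            rate = 1.0 / dt[0]
        else:
            rate = 30.0
        clean = df["clean_mm"].to_numpy() if "clean_mm" in df.columns else None
        return cls(df["position_mm"].to_numpy(), sample_rate_hz=rate, clean=clean)


@dataclass(frozen=True)
class BreathingSpec:
    """Parameters of one synthetic breathing pattern.

    Ranges are validated against clinical observation: bpm in [3, 20],
    amplitude in [5, 30] mm, duration in [60, 240] s at 30 Hz.
    ``shape_p`` is the waveform shape exponent (1 = sinusoid, >1 gives a
    flattened exhale plateau); ``irregularities`` is a sequence of
    (kind, params) pairs applied in order before noise.
    """

    bpm: float = 12.0
    amplitude_mm: float = 15.0
    duration_s: float = 120.0
    sample_rate_hz: float = 30.0
    shape_p: float = 2.0
    baseline_mm: float = 0.0
    noise_sd_mm: float = 0.1
    irregularities: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = BPM_RANGE
        if not lo <= self.bpm <= hi:
            raise InvalidParameterError(f"bpm must be in [{lo}, {hi}], got {self.bpm}")
        lo, hi = AMPLITUDE_RANGE_MM
        if not lo <= self.amplitude_mm <= hi:
            raise InvalidParameterError(
                f"amplitude_mm must be in [{lo}, {hi}], got {self.amplitude_mm}"
            )
        lo, hi = DURATION_RANGE_S
        if not lo <= self.duration_s <= hi:
            raise InvalidParameterError(
                f"duration_s must be in [{lo}, {hi}], got {self.duration_s}"
            )
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample_rate_hz must be > 0")
        if self.shape_p <= 0:
            raise InvalidParameterError("shape_p must be > 0")
        if self.noise_sd_mm < 0:
            raise InvalidParameterError("noise_sd_mm must be >= 0")
        for kind, _ in self.irregularities:
            if kind not in IRREGULARITY_KINDS:
                raise InvalidParameterError(
                    f"unknown irregularity {kind!r}; valid kinds: {IRREGULARITY_KINDS}"
                )

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sample_rate_hz)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "bpm", "amplitude_mm", "duration_s", "sample_rate_hz", "shape_p",
            "baseline_mm", "noise_sd_mm", "seed")}
        d["irregularities"] = [[k, dict(p)] for k, p in self.irregularities]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BreathingSpec":
        d = json.loads(text)
        d["irregularities"] = tuple((k, dict(p)) for k, p in d.pop("irregularities", []))
        return cls(**d)


def generate_base(spec: BreathingSpec) -> MotionTrace:
    """Clean quasi-sinusoidal waveform: baseline + A*((1+cos)/2)**p.

    The trace starts at an inhale peak, completes exactly
    bpm * duration/60 cycles, and satisfies max|y - baseline| = A.
    """
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    f = spec.bpm / 60.0
    cycle = (1.0 + np.cos(2.0 * np.pi * f * t)) / 2.0
    pos = spec.baseline_mm + spec.amplitude_mm * cycle**spec.shape_p
    return MotionTrace(pos, sample_rate_hz=spec.sample_rate_hz)


def _reference_baseline(pos: np.ndarray, params: dict) -> float:
    return float(params.get("baseline_mm", pos.min()))


def _apply_irregularity(
    pos: np.ndarray, rate: float, kind: str, params: dict, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(pos.size) / rate
    duration = pos.size / rate
    if kind == "amplitude_drift":
        # multiplicative envelope on the excursion above the resting level
        base = _reference_baseline(pos, params)
        factor = float(params.get("factor", 0.5))
        env = np.linspace(1.0, factor, pos.size)
        return base + (pos - base) * env
    if kind == "frequency_drift":
        # phase time-warp: playback starts slower and ends faster by a factor
        # (1+2r)/1 across the trace, normalized to preserve the endpoints
        r = float(params.get("rate_change", 0.3))
        T = max(duration, 1e-12)
        warped = t * (1.0 + r * t / T) / (1.0 + r)
        return np.interp(warped, t, pos)
    if kind == "pulse":
        amp = float(params.get("amplitude_mm", 5.0))
        width = float(params.get("width_s", 0.5))
        center = float(params.get("center_s", duration / 2.0))
        center = t[np.argmin(np.abs(t - center))]  # snap to the grid
        return pos + amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    if kind == "baseline_shift":
        shift = float(params.get("shift_mm", 5.0))
        t0 = float(params.get("at_s", duration / 2.0))
        ramp = float(params.get("ramp_s", 0.0))
        if ramp <= 0:
            return pos + shift * (t >= t0)
        return pos + shift * np.clip((t - t0) / ramp, 0.0, 1.0)
    if kind == "double_breathe":
        # secondary half-amplitude peak at the exhale phase of every cycle
        base = _reference_baseline(pos, params)
        period = float(params.get("period_s", _dominant_period(pos, rate)))
        amp = float(params.get("amplitude_mm", 0.5 * (pos.max() - base)))
        phase = (t % period) - period / 2.0
        return pos + amp * np.exp(-0.5 * (phase / (period / 10.0)) ** 2)
    if kind == "inverse_shape":
        about = float(params.get("about_mm", pos.mean()))
        return 2.0 * about - pos
    raise InvalidParameterError(
        f"unknown irregularity {kind!r}; valid kinds: {IRREGULARITY_KINDS}"
    )


def _dominant_period(pos: np.ndarray, rate: float) -> float:
    """Breathing period from the dominant nonzero Fourier component."""
    spectrum = np.abs(np.fft.rfft(pos - pos.mean()))
    freqs = np.fft.rfftfreq(pos.size, d=1.0 / rate)
    k = int(np.argmax(spectrum[1:]) + 1)
    return 1.0 / freqs[k]


def inject_irregularity(
    trace: MotionTrace, kind: str, params: dict | None = None, seed: int = 0
) -> MotionTrace:
    """Apply one named waveform irregularity; deterministic per seed.

    The same transformation is applied to the retained clean trace, since
    irregularities are genuine motion, not sensor artifacts.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    pos = _apply_irregularity(trace.positions, trace.sample_rate_hz, kind, params, rng)
    clean = None
    if trace.clean is not None:
        clean = _apply_irregularity(trace.clean, trace.sample_rate_hz, kind, params,
                                    np.random.default_rng(seed))
    return MotionTrace(pos, trace.sample_rate_hz, clean=clean)


def add_sensor_noise(trace: MotionTrace, sd_mm: float, seed: int = 0) -> MotionTrace:
    """Additive i.i.d. Gaussian sensor noise; the clean trace is retained."""
    if sd_mm < 0:
        raise InvalidParameterError(f"sd_mm must be >= 0, got {sd_mm}")
    if sd_mm == 0:
        return trace
    rng = np.random.default_rng(seed)
    noisy = trace.positions + rng.normal(0.0, sd_mm, trace.positions.size)
    clean = trace.clean if trace.clean is not None else trace.positions.copy()
    return MotionTrace(noisy, trace.sample_rate_hz, clean=clean)


def gaussian_filter(
    trace: MotionTrace, sigma_samples: float, causal: bool = False
) -> MotionTrace:
    """Gaussian denoising of the position stream.

    The default is a zero-phase FIR Gaussian (kernel truncated at 4 sigma,
    reflected edges), matching offline preprocessing of a recorded trace.
    ``causal=True`` instead convolves with the one-sided half kernel so no
    future samples are used — appropriate for strict streaming simulation,
    at the cost of a group delay of roughly sigma samples.
    """
    if sigma_samples <= 0:
        raise InvalidParameterError(f"sigma_samples must be > 0, got {sigma_samples}")
    pos = trace.positions
    if not causal:
        smoothed = scipy.ndimage.gaussian_filter1d(
            pos, sigma_samples, mode="reflect", truncate=4.0
        )
    else:
        half = int(np.ceil(4.0 * sigma_samples))
        k = np.exp(-0.5 * (np.arange(half + 1) / sigma_samples) ** 2)
        k /= k.sum()
        padded = np.concatenate([np.full(half, pos[0]), pos])
        smoothed = np.convolve(padded, k[::-1], mode="valid")
    return MotionTrace(smoothed, trace.sample_rate_hz, clean=trace.clean)


def generate(spec: BreathingSpec) -> MotionTrace:
    """Full generator: base waveform -> irregularities -> sensor noise."""
    trace = generate_base(spec)
    trace = MotionTrace(trace.positions, trace.sample_rate_hz,
                        clean=trace.positions.copy())
    for i, (kind, params) in enumerate(spec.irregularities):
        trace = inject_irregularity(trace, kind, params, seed=spec.seed + 1000 + i)
    trace = add_sensor_noise(trace, spec.noise_sd_mm, seed=spec.seed)
    return trace


def generate_cohort(
    n_traces: int = 76,
    seed: int = 0,
    bpm_range: tuple[float, float] = BPM_RANGE,
    amplitude_range_mm: tuple[float, float] = AMPLITUDE_RANGE_MM,
    duration_range_s: tuple[float, float] = DURATION_RANGE_S,
    sample_rate_hz: float = 30.0,
    noise_sd_mm: float = 0.1,
    irregularity_kinds: tuple = IRREGULARITY_KINDS,
    max_irregularities: int = 2,
) -> list[tuple[BreathingSpec, MotionTrace]]:
    """A cohort of breathing patterns spread over the clinical ranges.

    BPM values are laid out low-to-high across ``bpm_range``; amplitudes,
    durations and irregularity assignments (0 to ``max_irregularities``
    per trace) are drawn reproducibly from ``seed``.
    """
    if n_traces < 1:
        raise InvalidParameterError(f"n_traces must be >= 1, got {n_traces}")
    rng = np.random.default_rng(seed)
    bpms = np.linspace(bpm_range[0], bpm_range[1], n_traces)
    cohort = []
    for i, bpm in enumerate(bpms):
        irregs = []
        if irregularity_kinds and max_irregularities > 0:
            n_irr = rng.integers(0, max_irregularities + 1)
            for kind in rng.choice(irregularity_kinds, size=n_irr, replace=False):
                irregs.append((str(kind), {}))
        spec = BreathingSpec(
            bpm=float(bpm),
            amplitude_mm=float(rng.uniform(*amplitude_range_mm)),
            duration_s=float(rng.uniform(*duration_range_s)),
            sample_rate_hz=sample_rate_hz,
            shape_p=float(rng.uniform(1.0, 3.0)),
            noise_sd_mm=noise_sd_mm,
            irregularities=tuple(irregs),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append((spec, generate(spec)))
    return cohort
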