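# Methods

## Reservoir model

The simulator implements the discrete dynamics of a time-multiplexed
delay-line reservoir. One nonlinearity with a sinusoidal transfer
function (in hardware, a Mach–Zehnder modulator) serves N′ virtual nodes
laid out as time slots of width θ along a loop of round-trip delay τ.
Each sensor sample u(n) is sampled-and-held for the input period τ′ and
multiplied by a piecewise-constant random mask m(t) with period τ′, so
node i receives drive β·mᵢ·u(n). The canonical model is the flat slot
recurrence

    s_g = sin(α·s_{g−N} + β·m_{g mod N′}·u_{⌊g/N′⌋} + φ),   g = n·N′ + i,

with N = τ/θ and N′ = τ′/θ. When τ′ = τ (k_N = N − N′ = 0) this is the
classical synchronized per-node recurrence
xᵢ(n) = sin(α·xᵢ(n−1) + β·mᵢ·u(n) + φ); when τ′ < τ each node's feedback
comes from a shifted node of an earlier pass (node i−k_N of step n−1 for
i ≥ k_N, node i+N′−k_N of step n−2 otherwise), which desynchronizes and
enriches the dynamics at no extra state cost. The production stepping is
vectorized over nodes and over sliding windows; the test suite holds it
bit-identical to the scalar slot-stream recurrence above.

Assumptions and deliberate simplifications:

- States are sampled once per node per input step (end of the node's θ
  slot). Band-limited transient interaction between adjacent slots
  (photodetector bandwidth) is not modeled; the discrete recurrence is
  the computational model.
- The loop's internal connectivity is realized implicitly as the
  slot-shift induced by k_N (a delayed permutation), not as an explicit
  dense matrix — this is what a physical delay loop computes.
- Continuous-time θ, τ, τ′ enter only through N = τ/θ and N′ = τ′/θ,
  validated integral to 1e−9.
- The undriven loop settles to the scalar fixed point x* = sin(αx* + φ);
  for α < 1 the map is contracting, giving the echo-state/fading-memory
  property (verified: trajectories from opposite initial states agree to
  < 1e−6 after 200 steps).

### Spike-train characterization

The decaying-memory spike train drives a quiescent loop with one isolated
pulse and records the peak deviation per **loop round trip**, i.e. per
band of N slots in the flat slot stream. Under desynchronization the
per-input-step (τ′) peak sequence does not decay geometrically — the
two-step-back feedback path re-injects older, larger echoes into the
first k_N nodes — while the per-τ band sequence decays exactly at ratio
α·cos(operating point) in the linearized regime. With φ = 0 and a small
pulse the measured ratio equals α (0.8700 at α = 0.87 in
`examples/01_spike_train.py`).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| α | 0.87 | — | feedback (loop) gain; < 1 gives fading memory |
| β | 2.29 | — | input gain on the masked drive |
| φ | 0.55π | rad | nonlinearity bias phase (operating point just past the transfer peak) |
| θ | 2 | ns | virtual-node separation |
| τ | 28 | ns | loop round-trip delay → N = 14 |
| τ′ | 24 | ns | input hold time → N′ = 12, k_N = 2 |
| λ | 0.01 | — | ridge regularization |
| mask | binary ±1, seeded | — | per-node input weights |
| input_scale | 60 | mm | sensor-to-drive full scale (below) |
| k_tr | 600 | samples | training window (20 s at 30 Hz) |
| k_w | 15 | samples | input window driving the prediction feature |
| h_p | 10 (also 2, 5) | samples | look-ahead = 66.6/166.6/333 ms |

### Mask

The mask distribution is a free choice in delay-line reservoirs; binary
±1 levels are the default (maximal drive diversity at unit magnitude,
standard in the literature), with a uniform [−1, 1] option. The mask is
reproduced from a recorded seed so every run is exactly repeatable.

### Input full scale

A physical implementation converts sensor millimeters to a drive voltage
with a fixed gain before the nonlinearity. The simulator makes this
explicit: traces are divided by `input_scale_mm` (default 60 mm) where
they drive the loop. The value is chosen so the largest clinically
observed amplitude (30 mm) maps to a peak phase swing β·30/60 ≈ 1.15 rad
about the operating point — within one monotonic flank of the sinusoidal
transfer function while still engaging its curvature. Without such a
scale (or equivalently with a scale near the motion amplitude itself)
large traces fold the nonlinearity over several periods and prediction
collapses; at 45–150 mm performance is flat, so 60 mm is not a sensitive
tuning.

## Readout and online training

The readout solves W_out = Y Xᵀ (X Xᵀ + λI)⁻¹ as a symmetric linear
system (never an explicit inverse); λ = 0 on a rank-deficient Gram matrix
raises an error directing the user to λ > 0. There is no intercept by
default — the readout operates on raw, possibly non-zero-mean positions,
matching a linear combination of reservoir states; a bias row can be
enabled by flag (the reservoir-less baseline enables it by default, since
a 1-feature regression through the origin on absolute mm positions would
be structurally crippled).

The **dual-sliding-window** protocol: after the stream holds k_tr
samples, every new sample n triggers (1) a fresh ridge solve on the
training pairs of the current window and (2) a prediction for index
n + h_p from the input window ending at n. Training pairs are
(state(j), y_{j+h_p}) for every index j whose k_w input window and whose
target both lie inside the training window, giving
k_tr − h_p − k_w + 1 = 576 columns at the defaults. The nominal window
length k_tr is not padded to: edge indices lack either a full input
window or an observed target, and the 576-column batch is the exact set
of fully observed pairs. Features are computed by re-driving a
zero-initialized reservoir over each k_w window ("windowed" mode): this
is the reading under which k_w is a meaningful hyperparameter, it makes
every feature depend on exactly the window it claims to, and the k_w
drive steps double as the state's washout from the zero initial
condition. A "continuous" mode (one reservoir running over the whole
trace) is provided for comparison. Retraining happens every sample;
replaying a recorded trace through the streaming path is deterministic
and causal (emissions provably unchanged by perturbing future samples).

Indices at the interfaces are 1-based, matching clinical log convention:
with k_tr = 600 and h_p = 10 the first prediction targets sample 610,
and after sample 601 arrives the training window is {y₂…y₆₀₁}.

## Baselines

- **Fixed-model RC** trains once on the first k_tr samples (20 s, or
  60 s via configuration) and never retrains; prediction features are
  identical to the real-time predictor's, so performance gaps isolate
  the frozen weights. Traces too short for the training window plus one
  look-ahead are excluded with a logged reason.
- **Ridge-only** keeps the dual-sliding-window retraining but regresses
  on the raw last-k_w samples (default k_w = 1) plus bias — no reservoir.
  Its feature matrix is asserted to be exactly the raw sample window.

The large-reservoir configuration (N = 325, N′ = 323) is a pure parameter
change (τ = 650 ns, τ′ = 646 ns at θ = 2 ns), with no special casing.

## Metrics

NMSE = Σ(ŷᵢ−yᵢ)² / Σ(ȳ−yᵢ)² with ȳ the scalar mean of the ground truth
over the evaluated span (so the mean predictor scores exactly 1); MAE is
the mean **absolute** deviation (a signed mean would cancel errors and
could go negative, contradicting its name and use); RMSE as usual. TBE
at margin m is 100 × #{AE < m}/n with strict inequality. All metrics are
computed over every emitted prediction of a session.

## Synthetic breathing generator

Real cohort data is not distributable, so the generator emulates its
statistical structure: quasi-sinusoidal peak-valley-peak cycles at 3–20
breaths/min, amplitudes 5–30 mm, durations 1–4 min at 30 Hz, with the
catalogued irregularity taxonomy (amplitude drift, frequency drift,
transient pulse, baseline shift, double-breathe secondary peak, inverse
shape) plus additive Gaussian sensor noise (default sd 0.1 mm,
sub-resolution for a mm-scale sensor). The clean waveform family is
baseline + A·((1+cos 2πft)/2)^p; the shape exponent p (default 2, drawn
1–3 in cohorts) produces the characteristic narrow inhale peak over a
flattened exhale plateau, while p = 1 is a pure sinusoid. The clean
pre-noise trace is retained with every generated trace so prediction
error can be compared against the noise floor, and every generator is
deterministic from its seed.

What the generator does **not** emulate: hysteresis between inhale and
exhale paths, cardiac-motion superposition, surrogate-to-internal-target
correlation error, sensor drop-outs, or genuinely chaotic pattern
switches. Passing cohort tests therefore demonstrates the algorithmic
properties (online adaptation, reservoir benefit, horizon/rate trends) on
clinically plausible waveforms — not clinical performance on patients.

The Gaussian denoising filter is a zero-phase FIR kernel truncated at 4σ
with reflected edges (default σ = 2 samples ≈ 67 ms, configurable); this
matches offline preprocessing of a recorded trace but is acausal, so a
strictly causal one-sided variant is provided for streaming simulation
(group delay ≈ σ samples). It is applied to a whole trace before replay
when enabled; sessions run unfiltered by default.

## Numerical choices

- Ridge solve: `scipy.linalg.solve(..., assume_a="sym")`; singularity and
  non-finite results surface as a dedicated error with guidance.
- Reservoir initial condition: zero slots; windowed features inherit a
  k_w-step washout by construction.
- Quiescent fixed point found by direct iteration to 1e−14 (contraction
  for α < 1).
- Integral-ratio validation of τ/θ and τ′/θ at 1e−9.
- Fewer training columns than features warns (underdetermined but
  regularized) rather than failing.
- Non-finite stream samples are rejected with a logged warning, leaving
  the stream state unchanged.

## Problem sizes

Cohort-level checks (in `tests/test_acceptance.py` and
`scripts/acceptance.py`) use 30-trace cohorts of 60–120 s traces — large
enough that the orderings of interest (real-time < fixed-model on regime
changes; reservoir < raw ridge; error growing with look-ahead and with
breathing rate) are stable across seeds, while one full run stays in the
low minutes on a single CPU. Single-session checks use 1–2 minute traces
(1800–3600 samples). Durations in generated cohorts default to the
clinical 60–240 s range; the reduced ranges above are explicit arguments
at the call sites.

## Known limitations

- The streaming predictor retains O(T) history in memory (trivial at
  clinical session lengths); the logical training window is always the
  last k_tr samples.
- Wall-clock latency per retrain (~0.2 ms here) is a software number and
  says nothing about the hardware real-time budget; it is logged, never
  asserted.
- NMSE on near-constant traces is ill-conditioned by construction
  (zero-variance ground truth raises a dedicated error rather than
  returning a misleading number).
- The BPM-vs-error trend on synthetic cohorts is positive but shallow;
  with heavy irregularities the irregularity type dominates the error
  budget, as it does across patients.
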