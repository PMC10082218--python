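"""The breathing-irregularity taxonomy and its effect on predictability.

Each irregularity kind is injected into the same clean 10 BPM waveform
and the real-time predictor is run over the result; the NMSE shows how
much each distortion degrades forecasting.
"""

from respirc import (
    BreathingSpec,
    RCParams,
    WindowConfig,
    add_sensor_noise,
    generate_base,
    inject_irregularity,
    nmse,
    run_session,
)
from respirc.synth import IRREGULARITY_KINDS

p, cfg = RCParams(), WindowConfig()
base = generate_base(BreathingSpec(bpm=10, amplitude_mm=15, duration_s=90))

clean = add_sensor_noise(base, 0.1, seed=0)
print(f"{'(none)':16s} NMSE {nmse(run_session(clean.positions, p, cfg)):.4f}")
for kind in IRREGULARITY_KINDS:
    trace = add_sensor_noise(inject_irregularity(base, kind), 0.1, seed=0)
    err = nmse(run_session(trace.positions, p, cfg))
    print(f"{kind:16s} NMSE {err:.4f}")

print(
    "\nTransient events (pulse, baseline shift) and shape changes raise the "
    "error most; the per-sample retraining keeps the model tracking after "
    "each distortion instead of failing for the rest of the session."
)
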