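"""Online retraining versus a frozen model and a reservoir-less regressor.

A breathing trace shifts its baseline by 8 mm at t = 60 s — after the
fixed model's one-and-only training window.  The real-time predictor
retrains every 33 ms and follows the shift; the fixed-model RC keeps
stale weights; the ridge-only regressor retrains but lacks the reservoir's
nonlinear memory.
"""

from respirc import (
    BreathingSpec,
    RCParams,
    WindowConfig,
    generate,
    mae,
    nmse,
    run_fixed_model,
    run_ridge_only,
    run_session,
)

spec = BreathingSpec(
    bpm=12, amplitude_mm=15, duration_s=120, noise_sd_mm=0.1, seed=7,
    irregularities=(("baseline_shift", {"shift_mm": 8.0, "at_s": 60.0}),),
)
trace = generate(spec).positions
p, cfg = RCParams(), WindowConfig(h_p=10)

for name, records in [
    ("real-time RC", run_session(trace, p, cfg)),
    ("fixed-model RC", run_fixed_model(trace, p, cfg)),
    ("ridge only", run_ridge_only(trace, cfg)),
]:
    print(f"{name:15s} NMSE {nmse(records):7.4f}   MAE {mae(records):6.3f} mm")

print(
    "\nThe sliding training window discards pre-shift samples within 20 s, "
    "so the real-time readout re-converges; the fixed model mispredicts "
    "by ~the shift size for the rest of the session."
)
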