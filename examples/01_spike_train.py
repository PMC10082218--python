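"""Decaying memory of the delay loop: the spike-train characterization.

A single input pulse is injected into a quiescent reservoir and the peak
deviation from the resting state is tracked over successive loop round
trips.  With feedback gain alpha < 1 the echoes decay geometrically; in
the linearized regime the ratio of consecutive echoes equals alpha — the
loop's short-term memory "decay ratio".
"""

import numpy as np

from respirc import RCParams, spike_train_response

p = RCParams(alpha=0.87, phi=0.0, input_scale_mm=1.0)
echoes = spike_train_response(p, pulse_amp=1e-3, n_echoes=8)

print("round trip | echo amplitude | ratio to previous")
for k, e in enumerate(echoes):
    ratio = f"{echoes[k] / echoes[k-1]:.4f}" if k else "   -  "
    print(f"{k:10d} | {e:.6e}  | {ratio}")

print(
    f"\nMean decay ratio {np.mean(echoes[1:] / echoes[:-1]):.4f} ~ alpha = {p.alpha}: "
    "one pulse is retained, attenuated by the feedback gain, on every pass "
    "around the loop — the reservoir's fading memory."
)
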