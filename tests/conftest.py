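import numpy as np
import pytest

from respirc import RCParams, WindowConfig


@pytest.fixture
def p_default() -> RCParams:
    """Bench-default reservoir: N=14, N'=12, k_N=2."""
    return RCParams()


@pytest.fixture
def p_unit() -> RCParams:
    """Defaults with unit input scale, for closed-form drive checks."""
    return RCParams(input_scale_mm=1.0)


@pytest.fixture
def p_sync() -> RCParams:
    """Synchronized loop (tau = tau', k_N = 0)."""
    return RCParams(tau_ns=24.0, tau_prime_ns=24.0, input_scale_mm=1.0)


@pytest.fixture
def sine_trace() -> np.ndarray:
    """Two minutes of a clean 15 BPM, 15 mm breathing sinusoid at 30 Hz."""
    t = np.arange(3600) / 30.0
    return 10.0 + 7.5 * np.sin(2 * np.pi * 0.25 * t)


def slot_stream_oracle(u, p: RCParams) -> np.ndarray:
    """Flat scalar simulation of the delay loop, slot by slot.

    Global slot g = n*N' + i takes its feedback from slot g - N; this is
    the reference dynamics every vectorized stepping scheme must match.
    """
    us = np.asarray(u, dtype=float) / p.input_scale_mm
    m = p.mask()
    n_loop, n_act = p.n_nodes, p.n_active
    s = np.zeros(us.size * n_act)
    for g in range(s.size):
        fb = s[g - n_loop] if g >= n_loop else 0.0
        s[g] = np.sin(p.alpha * fb + (p.beta * m[g % n_act]) * us[g // n_act] + p.phi)
    return s.reshape(us.size, n_act).T
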