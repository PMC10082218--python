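"""Time-multiplexed delay-line reservoir dynamics.

A single sinusoidal nonlinearity serves N' virtual nodes multiplexed in
time along a delay loop of capacity N nodes.  Each discrete input sample
u(n) is held for the input period tau' and modulated by the piecewise mask
m_i; node i of step n occupies the global time slot g = n*N' + i, and its
feedback arrives from the slot one full round trip (N slots) earlier:

    s_g = sin(alpha * s_{g-N} + beta * m_{g mod N'} * u_{floor(g/N')} + phi)

For the synchronized loop (k_N = N - N' = 0) this collapses to the usual
per-node recurrence x_i(n) = sin(alpha*x_i(n-1) + beta*m_i*u(n) + phi).
For k_N > 0 node i reads node i-k_N of the previous step when i >= k_N and
node i+N'-k_N of the step before that otherwise, which is what enriches
the dynamics of a desynchronized loop.

All states lie in [-1, 1] (range of the sine), and for alpha < 1 the map
is contracting, so the reservoir has fading memory: trajectories from
different initial conditions converge on a common input drive.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError, ShapeError, StateError
from .params import RCParams, make_mask

__all__ = [
    "make_mask",
    "step_synchronized",
    "step_desynchronized",
    "run_reservoir",
    "windowed_states",
    "spike_train_response",
    "quiescent_state",
]


def _check_state(x: np.ndarray, n_active: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n_active,):
        raise ShapeError(f"{name} must have shape ({n_active},), got {x.shape}")
    return x


def step_synchronized(
    x_prev: np.ndarray, u_n: float, p: RCParams, mask: np.ndarray | None = None
) -> np.ndarray:
    """One synchronized reservoir update x_i = sin(a*x_i + b*m_i*u + phi).

    This is the k_N = 0 dynamics where each node feeds back onto itself.
    """
    x_prev = _check_state(x_prev, p.n_active, "x_prev")
    if mask is None:
        mask = p.mask()
    return np.sin(p.alpha * x_prev + p.beta * mask * u_n + p.phi)


def step_desynchronized(
    slot_history: np.ndarray, u_n: float, p: RCParams, mask: np.ndarray | None = None
) -> np.ndarray:
    """One desynchronized update from the two previous state vectors.

    ``slot_history`` is a (2, N') array: row 0 is the state of step n-1,
    row 1 that of step n-2 (the last 2*N' >= N slots).  Node i reads its
    feedback from node i-k_N of step n-1 when i >= k_N, and from node
    i+N'-k_N of step n-2 otherwise.  Reduces exactly to
    :func:`step_synchronized` when k_N = 0.
    """
    slot_history = np.asarray(slot_history, dtype=float)
    n_active, k_n = p.n_active, p.k_n
    if slot_history.ndim != 2 or slot_history.shape[1] != n_active:
        raise ShapeError(
            f"slot_history must be (2, {n_active}), got {slot_history.shape}"
        )
    if slot_history.shape[0] < 2:
        raise StateError(
            "slot_history must cover the last two steps (>= N slots)"
        )
    x1, x2 = slot_history[0], slot_history[1]
    if mask is None:
        mask = p.mask()
    feedback = _feedback(x1, x2, k_n)
    return np.sin(p.alpha * feedback + p.beta * mask * u_n + p.phi)


def _feedback(x1: np.ndarray, x2: np.ndarray, k_n: int) -> np.ndarray:
    """Feedback vector one round trip (N slots) back, from steps n-1, n-2."""
    if k_n == 0:
        return x1
    # nodes 0..k_N-1 wrap past the start of step n-1 into step n-2
    return np.concatenate([x2[-k_n:], x1[: x1.shape[-1] - k_n]])


def run_reservoir(
    u: np.ndarray, p: RCParams, init: np.ndarray | None = None
) -> np.ndarray:
    """Drive the reservoir over an input segment; return the N' x T state matrix.

    Column n is the state after ingesting u[0..n].  The loop starts from
    zero slots unless ``init`` (an N'-vector replicated over the history)
    is given.  ``u`` is a sensor segment in mm and passes through the
    input full-scale mapping (division by ``p.input_scale_mm``) before
    masking; the step functions, by contrast, take the already-scaled
    drive value.
    """
    u = np.asarray(u, dtype=float).ravel() / p.input_scale_mm
    if u.size == 0:
        raise InvalidParameterError("input segment must be non-empty")
    n_active = p.n_active
    mask = p.mask()
    if init is None:
        x1 = np.zeros(n_active)
        x2 = np.zeros(n_active)
    else:
        x1 = _check_state(init, n_active, "init").copy()
        x2 = x1.copy()
    states = np.empty((n_active, u.size))
    a, b, phi, k_n = p.alpha, p.beta, p.phi, p.k_n
    bm = b * mask
    for n, u_n in enumerate(u):
        x_new = np.sin(a * _feedback(x1, x2, k_n) + bm * u_n + phi)
        states[:, n] = x_new
        x2, x1 = x1, x_new
    return states


def windowed_states(trace: np.ndarray, p: RCParams, k_w: int) -> np.ndarray:
    """States of a fresh k_w-sample drive ending at every admissible index.

    For each 1-based index j in [k_w, len(trace)] a zero-initialized
    reservoir is driven with trace[j-k_w .. j-1] (0-based) and its final
    state kept.  Returns an (N', len(trace) - k_w + 1) matrix whose column
    c corresponds to j = k_w + c.  All windows are advanced in lock-step,
    so the cost is k_w vectorized updates regardless of trace length.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if k_w < 1:
        raise InvalidParameterError(f"k_w must be >= 1, got {k_w}")
    if trace.size < k_w:
        raise InvalidParameterError(
            f"trace of length {trace.size} shorter than window k_w={k_w}"
        )
    trace = trace / p.input_scale_mm
    n_win = trace.size - k_w + 1
    n_active = p.n_active
    mask = p.mask()
    a, phi, k_n = p.alpha, p.phi, p.k_n
    bm = (p.beta * mask)[:, None]
    x1 = np.zeros((n_active, n_win))
    x2 = np.zeros((n_active, n_win))
    for t in range(k_w):
        u_t = trace[t : t + n_win]  # sample t of every window, shape (n_win,)
        if k_n == 0:
            fb = x1
        else:
            fb = np.concatenate([x2[-k_n:], x1[: n_active - k_n]], axis=0)
        x_new = np.sin(a * fb + bm * u_t[None, :] + phi)
        x2, x1 = x1, x_new
    return x1


def quiescent_state(p: RCParams, tol: float = 1e-14, max_iter: int = 10_000) -> float:
    """Fixed point x* = sin(alpha*x* + phi) of the undriven reservoir.

    With u = 0 every node settles to the same scalar value; for alpha < 1
    the iteration is a contraction and converges geometrically.
    """
    x = 0.0
    for _ in range(max_iter):
        x_new = float(np.sin(p.alpha * x + p.phi))
        if abs(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def spike_train_response(
    p: RCParams, pulse_amp: float = 0.1, n_echoes: int = 10
) -> np.ndarray:
    """Echo amplitudes of one isolated input pulse circulating the loop.

    The reservoir is settled to its quiescent fixed point, driven with a
    single sample of amplitude ``pulse_amp`` followed by zeros, and the
    peak deviation |s_g - x*| is taken over each successive round trip
    (band of N slots in the flat slot stream).  The resulting sequence is
    the decaying-memory spike train; in the linearized regime (phi = 0,
    small pulse) consecutive echo ratios approach alpha.
    """
    if n_echoes < 2:
        raise InvalidParameterError(f"n_echoes must be >= 2, got {n_echoes}")
    n, n_active = p.n_nodes, p.n_active
    x_star = quiescent_state(p)
    n_slots_needed = n_echoes * n
    n_steps = -(-n_slots_needed // n_active) + 1  # ceil + margin
    u = np.zeros(n_steps)
    u[0] = pulse_amp
    init = np.full(n_active, x_star)
    states = run_reservoir(u, p, init=init)
    slots = states.ravel(order="F")  # slot g = n*N' + i
    dev = np.abs(slots - x_star)
    echoes = np.array(
        [dev[k * n : (k + 1) * n].max() for k in range(n_echoes)]
    )
    return echoes
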