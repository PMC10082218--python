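"""Exception hierarchy for respirc.

All errors derive from :class:`RespircError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the pipeline (bad parameters, shape mismatches,
insufficient stream history, sessions too short to predict).
"""


class RespircError(Exception):
    """Base class for all respirc errors."""


class InvalidParameterError(RespircError, ValueError):
    """A parameter value is outside its valid domain."""


class ShapeError(RespircError, ValueError):
    """An array argument has an incompatible shape or length."""


class StateError(RespircError, RuntimeError):
    """The stream/reservoir lacks the history required for this operation."""


class WindowUnderflowError(RespircError, ValueError):
    """An index does not have a full input window behind it."""


class SessionTooShortError(RespircError, ValueError):
    """The trace is too short to emit a single prediction."""


class SingularSystemError(RespircError, RuntimeError):
    """The ridge normal equations are singular.

    Raised when ``lambda_reg == 0`` and the state Gram matrix is rank
    deficient; setting ``lambda_reg > 0`` (the default 0.01) regularizes
    the solve.
    """


class MetricUndefinedError(RespircError, ValueError):
    """A metric is undefined on this input (e.g. zero-variance ground truth)."""
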