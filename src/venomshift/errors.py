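"""Exception hierarchy shared across the package.

All errors derive from :class:`VenomShiftError` so callers can catch the
package's failures with a single ``except`` clause while still
distinguishing data problems from numerical ones.
"""


class VenomShiftError(Exception):
    """Base class for all package errors."""


class DegenerateSampleError(VenomShiftError, ValueError):
    """A sample (row) carries no usable signal, e.g. an all-zero row."""


class InsufficientDataError(VenomShiftError, ValueError):
    """Too few samples/points for the requested analysis."""


class ParameterError(VenomShiftError, ValueError):
    """A tuning parameter is outside its valid domain."""


class DegenerateDesignError(VenomShiftError, ValueError):
    """The regression/permutation design is uninformative (constant predictor)."""


class ConvergenceError(VenomShiftError, RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""


class ValidationError(VenomShiftError, ValueError):
    """Structural validation of an input object failed."""
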