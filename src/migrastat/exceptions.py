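"""Exception hierarchy.

All errors raised by migrastat derive from :class:`MigrastatError`, so callers
can catch package failures without masking programming errors. Analysis stages
distinguish *insufficient* data (series too short for the requested scales)
from *degenerate* data (e.g. a constant series, for which a scaling exponent
is undefined); pipeline drivers treat both as "metric unavailable for this
cell" rather than fatal.
"""


class MigrastatError(Exception):
    """Base class for all migrastat errors."""


class ConfigurationError(MigrastatError):
    """A required column, option or group assignment could not be resolved."""


class ValidationError(MigrastatError):
    """Input data violates a structural invariant (e.g. duplicate frames)."""


class EmptyInputError(MigrastatError):
    """An input file or collection contained no usable records."""


class InsufficientDataError(MigrastatError):
    """The series/trajectory is too short for the requested computation."""


class DegenerateInputError(MigrastatError):
    """The input admits no meaningful estimate (constant series, no motion)."""


class ParameterError(MigrastatError, ValueError):
    """A parameter is outside its admissible range."""


class GapWarning(UserWarning):
    """A track contains missing frames; the step spans the gap."""
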