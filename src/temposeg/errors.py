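"""Exception hierarchy used across the package."""


class TempoSegError(Exception):
    """Base class for all package-specific errors."""


class MovieIOError(TempoSegError, IOError):
    """A movie or mask file could not be read or written."""


class DimensionError(TempoSegError, ValueError):
    """Input array has the wrong number of dimensions or an incompatible shape."""


class WindowRangeError(TempoSegError, ValueError):
    """A requested frame window extends beyond the movie."""


class ParameterError(TempoSegError, ValueError):
    """A parameter is outside its valid range."""


class ValidationError(TempoSegError, ValueError):
    """A domain object violates one of its invariants."""


class EmptySelectionError(TempoSegError, RuntimeError):
    """No confident points survived at the requested discount factor."""


class AmbiguousClusterError(TempoSegError, RuntimeError):
    """The object/background identity of the two clusters cannot be decided."""


class ConvergenceError(TempoSegError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class GeometryError(TempoSegError, ValueError):
    """A synthetic shape or polygon ROI is geometrically invalid for the frame."""
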