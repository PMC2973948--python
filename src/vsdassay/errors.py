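"""Exception hierarchy shared across the package."""


class VsdAssayError(Exception):
    """Base class for all package-specific errors."""


class DomainError(VsdAssayError, ValueError):
    """An argument lies outside its mathematical domain (e.g. a gate outside [0, 1])."""


class NumericalInstabilityError(VsdAssayError, ArithmeticError):
    """The integrator produced a non-finite state; carries the offending time."""

    def __init__(self, message: str, time_ms: float | None = None, step: int | None = None):
        super().__init__(message)
        self.time_ms = time_ms
        self.step = step


class GeometryError(VsdAssayError, ValueError):
    """Invalid culture geometry (self-intersection, overlap, out-of-domain feature)."""

    def __init__(self, message: str, vertex_index: int | None = None):
        super().__init__(message)
        self.vertex_index = vertex_index


class ConfigurationError(VsdAssayError, ValueError):
    """A run configuration block fails validation."""


class LocationError(VsdAssayError, ValueError):
    """A query point lies outside the meshed domain."""


class ProtocolError(VsdAssayError, ValueError):
    """Invalid stimulation protocol (non-positive duration, inconsistent timing)."""


class CoverageError(VsdAssayError, ValueError):
    """A voltage trace does not cover the requested movie duration."""


class DataError(VsdAssayError, ValueError):
    """Input data violates a precondition (e.g. non-positive baseline fluorescence)."""


class UndefinedStatisticError(VsdAssayError, ZeroDivisionError):
    """A ratio statistic has an empty denominator (no suprathreshold pixels)."""


class DegenerateRangeError(VsdAssayError, ValueError):
    """An image with no intensity range cannot be contrast-normalized."""


class ThresholdUnreachableError(VsdAssayError, RuntimeError):
    """No amplitude within the allowed range depolarizes every cell past threshold."""

    def __init__(self, message: str, limiting_cell: int):
        super().__init__(message)
        self.limiting_cell = limiting_cell
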