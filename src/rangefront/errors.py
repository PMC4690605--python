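"""Exception types shared across the engines."""


class RangefrontError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(RangefrontError, ValueError):
    """Obstacle or environment geometry violates a precondition."""


class OutOfDomainError(RangefrontError, ValueError):
    """A query point lies outside the rectangular habitat."""


class PackingError(RangefrontError, RuntimeError):
    """Random obstacle field could not be packed without overlap.

    Carries the number of rejection-sampling attempts made.
    """

    def __init__(self, message: str, attempts: int = 0):
        super().__init__(message)
        self.attempts = attempts


class NotYetFormedError(RangefrontError, ValueError):
    """A kink/cusp quantity was requested before the feature exists.

    Carries ``d_kink``, the front position at which the feature forms.
    """

    def __init__(self, message: str, d_kink: float):
        super().__init__(message)
        self.d_kink = d_kink


class EmptyFrontError(RangefrontError, ValueError):
    """A requested level set does not intersect the grid interior."""


class NotApplicableError(RangefrontError, ValueError):
    """The measurement is undefined for this input (e.g. no contact point)."""


class AlignmentError(RangefrontError, ValueError):
    """Two series could not be aligned on a common grid."""


class MeasurementError(RangefrontError, ValueError):
    """A front measurement window contained no usable vertices."""


class ParameterError(RangefrontError, ValueError):
    """A physical parameter is out of its admissible range."""


class ConfigError(RangefrontError, ValueError):
    """A run configuration failed schema validation."""


class IntegrationError(RangefrontError, RuntimeError):
    """The method-of-lines integrator failed to meet its tolerances."""


class StallError(RangefrontError, RuntimeError):
    """A stochastic run cannot reach its stop condition."""


class NotReadyError(RangefrontError, ValueError):
    """A statistic was requested before the front has advanced far enough."""
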