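"""Exception hierarchy used across the package."""


class TdfretError(Exception):
    """Base class for all package-specific errors."""


class GridError(TdfretError):
    """Time grid is non-uniform, non-increasing, or mismatched between records."""


class FormatError(TdfretError):
    """A histogram file violates the two-column text contract."""


class ConfigurationError(TdfretError):
    """A model/quadrature configuration is unusable (e.g. truncated density mass)."""


class DegenerateDataError(TdfretError):
    """Observed data carry no usable signal (e.g. all-zero trace, empty IRF)."""


class SpecError(TdfretError):
    """A fit specification is malformed (bad sharing map, broken linkage, ...)."""


class ConvergenceError(TdfretError):
    """Optimization failed to converge; carries the best attempt found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class UnidentifiableError(TdfretError):
    """The requested parameter cannot be determined from the given data."""
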