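"""Exception hierarchy for spindyn."""


class SpinDynError(Exception):
    """Base class for all spindyn errors."""


class InvalidParameterError(SpinDynError, ValueError):
    """A physical parameter is outside its valid range."""


class FitError(SpinDynError, RuntimeError):
    """A least-squares fit failed to converge; carries residual diagnostics."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class CoverageError(SpinDynError, ValueError):
    """A frequency or temperature axis does not cover the requested feature."""


class UnresolvedPatternError(SpinDynError, ValueError):
    """A dipolar pattern has no two resolvable horns (fast-motion limit?)."""


class NoSolutionError(SpinDynError, ValueError):
    """A rate inversion was requested above the model's maximum achievable rate."""


class WindowError(SpinDynError, ValueError):
    """Insufficient data inside the requested analysis window."""


class FormatError(SpinDynError, ValueError):
    """A structure or spectrum file could not be parsed."""
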