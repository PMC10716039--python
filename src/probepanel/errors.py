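"""Exception and warning types shared across the package."""


class ProbePanelError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleLibraryError(ProbePanelError):
    """Raised when a barcode library request cannot satisfy its distance constraint."""


class UndersampledEventError(ProbePanelError):
    """Raised when an event has fewer samples than the number of bins requested."""


class SaturatedCurveError(ProbePanelError):
    """Raised when a percent-delay reading is at or above the curve's saturation level."""


class FitFailureError(ProbePanelError):
    """Raised when a standard-curve fit does not converge.

    Carries residual diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class ConfigError(ProbePanelError):
    """Raised on invalid run configuration; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = list(errors)


class FlatCurveWarning(UserWarning):
    """Emitted when dose-response data show no rise above background."""


class BelowBackgroundWarning(UserWarning):
    """Emitted when a percent-delay reading falls below the fitted background."""


class ParameterRangeWarning(UserWarning):
    """Emitted when a tunable parameter is outside its recommended range."""
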