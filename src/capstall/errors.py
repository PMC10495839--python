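"""Exception hierarchy.

Every error raised by capstall derives from :class:`CapstallError`, so callers
(and the CLI) can catch the package's failures without masking programming
errors.
"""


class CapstallError(Exception):
    """Base class for all capstall errors."""


class ConfigurationError(CapstallError, ValueError):
    """A configuration value violates its constraints."""


class ValidationError(CapstallError, ValueError):
    """An input object violates a documented precondition or invariant."""


class FormatError(CapstallError, ValueError):
    """A file on disk does not match the expected format."""


class NoVesselNearClickError(CapstallError):
    """No graph edge lies within the allowed distance of a click."""

    def __init__(self, click, min_distance, max_distance):
        self.click = click
        self.min_distance = min_distance
        self.max_distance = max_distance
        super().__init__(
            f"nearest vessel pixel is {min_distance:.1f} px from click {click}, "
            f"beyond the allowed {max_distance:.1f} px"
        )


class RegistrationDegenerateError(CapstallError):
    """Registration crop is too small to estimate a shift."""


class UnbracketedFWHMError(CapstallError):
    """An intensity profile never crosses half-maximum on one side."""


class DegenerateBaselineError(CapstallError):
    """The fluorescence baseline F0 is zero; dF/F is undefined."""


class FitError(CapstallError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message, params=None, residual_norm=None):
        self.params = params
        self.residual_norm = residual_norm
        super().__init__(message)
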