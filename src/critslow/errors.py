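"""Exception hierarchy.

All domain errors derive from :class:`CritslowError`; user-facing tools map
them to exit code 1, anything else to 2.
"""


class CritslowError(Exception):
    """Base class for all critslow errors."""


class ConfigError(CritslowError):
    """Invalid configuration value or inconsistent configuration."""


class IntegrationError(CritslowError):
    """SDE integration failed (non-finite state or unstable step size)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class NoEquilibriumError(CritslowError):
    """No stable equilibrium exists at the requested control-parameter value."""


class UnsupportedKindError(CritslowError):
    """Operation does not apply to this bifurcation kind."""


class EmptySeriesError(CritslowError):
    """No usable perturbation events before onset."""


class DegenerateFitError(CritslowError):
    """Segment carries no signal to fit (e.g. constant)."""


class UndefinedACFError(CritslowError):
    """Autocorrelation undefined (zero-variance segment)."""


class UnstableNormalizationError(CritslowError):
    """Lag-1 autocorrelation too close to zero for stable normalization."""


class InsufficientBaselineError(CritslowError):
    """Less than one second of recording available before onset."""


class InsufficientDataError(CritslowError):
    """Fewer qualifying samples than the fit requires."""


class AllFitsRejectedError(CritslowError):
    """Every power-law fit in the cutoff sweep fell below the R^2 threshold."""

    def __init__(self, message: str, fits=None):
        super().__init__(message)
        self.fits = fits or []


class UnclassifiableError(CritslowError):
    """Bifurcation classification impossible from the given estimates."""


class PredictionFailedError(CritslowError):
    """Nonlinear tipping-point fit did not converge."""


class UndefinedCorrelationError(CritslowError):
    """Across-trial correlation undefined (zero-variance predictor)."""
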