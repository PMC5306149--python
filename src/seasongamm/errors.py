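"""Exception hierarchy for seasongamm."""


class SeasongammError(Exception):
    """Base class for all package errors."""


class ConfigError(SeasongammError):
    """A required column, option or label mapping is missing or malformed."""


class ValidationError(SeasongammError):
    """Input data violate a stated invariant (bad species label, bad counts...)."""


class DegenerateInputError(SeasongammError):
    """Too little structure in the input for the requested operation."""


class RangeError(SeasongammError):
    """Evaluation points fall outside the supported interval."""


class DecompositionError(SeasongammError):
    """A matrix factorization did not have the expected rank structure."""


class SpecError(SeasongammError):
    """Model specification cannot be assembled from the given records."""


class InitializationError(SeasongammError):
    """The sampler could not find a finite starting state."""


class ExtrapolationError(SeasongammError):
    """A posterior curve was requested outside the fitted day range."""


class GlmError(SeasongammError):
    """GLM fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class FixtureError(SeasongammError):
    """Fixture constraints are infeasible; names the first violated margin."""


class UndefinedResultError(SeasongammError):
    """The requested statistic is undefined for this fit (e.g. zero null deviance)."""
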