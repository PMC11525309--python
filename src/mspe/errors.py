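"""Typed exceptions shared across the package."""


class MSPEError(Exception):
    """Base class for all package-specific errors."""


class InvalidEffectError(MSPEError):
    """An effect specification is not usable (e.g. non-positive SE scale)."""


class SeparationError(MSPEError):
    """Binary outcomes are perfectly (or quasi-) separated by the predictor.

    ML coefficients diverge in this situation; the remedy is to widen the
    range of simulated sample sizes so that both significant and
    non-significant decisions occur throughout the n-range.
    """


class InversionError(MSPEError):
    """The fitted power curve cannot be inverted (slope <= 0)."""


class PowerCapError(MSPEError):
    """A target power rate above the supported evaluation cap was requested."""


class ExtrapolationError(MSPEError):
    """A prediction outside the naive method's sample-size grid was requested."""


class GridError(MSPEError):
    """The naive method requires records on exactly four distinct sample sizes."""


class NotAchievableError(MSPEError):
    """The confidence-band lower bound never reaches the target power."""


class FeasibilityError(MSPEError):
    """Moment targets outside the feasible region of the cubic transform."""


class SEMSpecError(MSPEError):
    """A structural equation model specification is malformed."""


class ConfigurationError(MSPEError):
    """A generation or study configuration is internally inconsistent."""


class RecordParseError(MSPEError):
    """A significance-decision log failed validation."""
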