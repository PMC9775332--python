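"""Exception hierarchy for sonokinetics.

All package-specific errors derive from :class:`SonokineticsError` so callers
can catch the whole family with one clause.
"""


class SonokineticsError(Exception):
    """Base class for all sonokinetics errors."""


class ParameterArityError(SonokineticsError, ValueError):
    """A coefficient vector does not match the model's parameter count."""


class DomainError(SonokineticsError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UnsupportedTransformError(SonokineticsError, TypeError):
    """A linearizing transform was requested for a direct-fit model."""


class MissingBaselineError(SonokineticsError, ValueError):
    """The baseline window contains too few samples to estimate Io."""


class DegenerateNormalizationError(SonokineticsError, ValueError):
    """Post-lysis intensity does not exceed the baseline (I_inf <= Io)."""


class PlateauNotFoundError(SonokineticsError, ValueError):
    """No interval after lysis satisfies the flatness criterion."""


class EmptyProfileError(SonokineticsError, ValueError):
    """De-stepping retained no samples inside any ultrasound-ON interval."""


class DataSizeError(SonokineticsError, ValueError):
    """A profile has too few points for the requested fit."""


class DegenerateDesignError(SonokineticsError, ValueError):
    """The polynomial design matrix is rank deficient."""


class EmptySelectionError(SonokineticsError, ValueError):
    """A study selection excluded every entry."""
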