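"""Exception hierarchy shared by all pipeline stages."""


class ProsoContrastError(Exception):
    """Base class for all package errors."""


class SchemaError(ProsoContrastError):
    """A required column or field is missing from an input table."""


class ValidationError(ProsoContrastError):
    """A record violates a domain invariant (e.g. non-positive duration)."""


class StructureError(ProsoContrastError):
    """A TextGrid tier does not follow the expected S1/S2 pairing."""


class AssociationError(ProsoContrastError):
    """An L/H point cannot be associated with a token or lies outside the
    PitchTier's sampled range."""


class JoinError(ProsoContrastError):
    """A token references a participant with no metadata record."""


class UndefinedStatisticError(ProsoContrastError):
    """A statistic is undefined for the given input (zero tokens, constant
    vector, zero pooled variance)."""


class ConvergenceError(ProsoContrastError):
    """Model estimation failed to converge and no fallback applies."""


class SeparationError(ProsoContrastError):
    """The binary outcome is constant (overall or within a design cell on
    which an effect is estimated), so logistic estimates diverge."""


class ComparisonError(ProsoContrastError):
    """Two model fits cannot be compared (different data)."""


class ConfigError(ProsoContrastError):
    """A generator or run configuration violates its invariants."""
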