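"""Exception hierarchy for monofilm."""


class MonofilmError(Exception):
    """Base class for all package-specific errors."""


class IsothermFormatError(MonofilmError):
    """The input file does not match a known isotherm dialect."""


class IsothermValidationError(MonofilmError):
    """The isotherm data violate a structural invariant (e.g. non-monotone
    area that sorting cannot repair)."""


class InsufficientDataError(MonofilmError):
    """Too few valid samples to run the requested operation."""


class SmoothingConfigError(MonofilmError):
    """Smoothing window incompatible with the signal length."""


class ParameterInfeasibleError(MonofilmError):
    """Synthetic-isotherm parameters cannot produce the requested phase
    sequence (e.g. the Volmer branch cannot reach the plateau onset
    pressure before the minimum area)."""


class PresetLookupError(MonofilmError, LookupError):
    """Unknown (lipid, subphase) preset combination."""


class MissingControlError(MonofilmError):
    """A comparison was requested for a lipid without a water-control row."""


class UndefinedComparisonError(MonofilmError):
    """Fold/percent reduction is undefined for the given operands."""


class AggregationError(MonofilmError):
    """Feature-table assembly failed (e.g. duplicate keys)."""
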