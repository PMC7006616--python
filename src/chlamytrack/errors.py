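"""Exception hierarchy for chlamytrack."""


class ChlamyTrackError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChlamyTrackError, ValueError):
    """Invalid input data or parameter values."""


class ConfigurationError(ChlamyTrackError, ValueError):
    """A configuration that cannot be executed (e.g. undetectable scale)."""


class UnknownStrainError(ChlamyTrackError, KeyError):
    """Strain identifier not found among the built-in presets."""


class InfeasibleAssignmentError(ChlamyTrackError, ValueError):
    """No finite-cost perfect assignment exists for the cost matrix."""


class IntegrityError(ChlamyTrackError, ValueError):
    """Cross-table or cross-structure referential inconsistency."""


class EmptyInputError(ChlamyTrackError, ValueError):
    """An operation that requires at least one element received none."""
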