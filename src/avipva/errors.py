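"""Exception types shared across the package."""


class AvipvaError(Exception):
    """Base class for package errors."""


class SchemaError(AvipvaError):
    """A vital-rate file does not follow the documented CSV schema."""


class ValidationError(AvipvaError):
    """A vital-rate record violates a domain invariant."""


class CalibrationError(AvipvaError):
    """Recruitment calibration cannot reach the requested growth rate."""


class PolicyUndefinedError(AvipvaError):
    """A removal policy is undefined for the given inputs (e.g. r0 <= 0)."""


class UndefinedStatisticError(AvipvaError):
    """A comparison statistic is undefined (e.g. zero baseline)."""


class GenerationError(AvipvaError):
    """Synthetic life-history generation failed for the given ranges."""
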