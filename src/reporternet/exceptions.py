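"""Exception hierarchy shared across the package."""


class ReporternetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ReporternetError, ValueError):
    """Input violates a documented precondition or invariant."""


class StructuralError(ValidationError):
    """Malformed container: non-rectangular matrix, dangling reference, ..."""


class ConfigurationError(ReporternetError):
    """Requested combination of inputs/labels cannot be satisfied."""


class DegenerateNullError(ReporternetError):
    """Background null has zero spread; corrected scores are undefined."""

    def __init__(self, size: int):
        self.size = size
        super().__init__(
            f"background null for subset size k={size} has sigma=0 "
            "(constant score pool); corrected scores are undefined"
        )


class InsufficientDataError(ReporternetError):
    """Too few usable observations for the requested fit."""
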