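"""Exception hierarchy shared across the package."""


class IristexError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IristexError):
    """Malformed input (bad JSON/CSV structure, missing or mistyped field)."""

    def __init__(self, message: str, field: str | None = None, row: int | None = None):
        self.field = field
        self.row = row
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class ValidationError(IristexError):
    """Well-formed input that violates a domain invariant."""


class ExclusionError(IristexError):
    """Record cannot be characterized and must be excluded."""

    def __init__(self, message: str, reason: str):
        self.reason = reason
        super().__init__(message)


class UndefinedStatisticError(IristexError):
    """A statistic is undefined for the given data (e.g. all ties)."""


class ConvergenceError(IristexError):
    """Iterative fit failed to converge."""

    def __init__(self, message: str, trace: list | None = None):
        self.trace = trace or []
        super().__init__(message)
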