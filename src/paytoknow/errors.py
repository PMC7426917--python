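"""Exception types shared across the package."""

__all__ = [
    "PayToKnowError",
    "InvalidConfigError",
    "SchemaError",
    "ValidationError",
    "NonConvergenceError",
    "UndefinedPSEError",
    "ZeroVarianceError",
]


class PayToKnowError(Exception):
    """Base class for package errors."""


class InvalidConfigError(PayToKnowError):
    """A configuration value is inconsistent or infeasible."""


class SchemaError(PayToKnowError):
    """A tabular input is missing required columns."""


class ValidationError(PayToKnowError):
    """A row-level value violates a domain invariant.

    Carries the 0-based row index of the offending row when known.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class NonConvergenceError(PayToKnowError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UndefinedPSEError(PayToKnowError):
    """The fitted psychometric curve never crosses 50%."""


class ZeroVarianceError(PayToKnowError):
    """A statistic is undefined because its inputs have zero variance."""
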