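"""Exception hierarchy shared across the package."""


class TroughVarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TroughVarError):
    """Input table does not conform to the expected schema."""


class RowValidationError(TroughVarError):
    """A single input row violates a value-level invariant."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class IntegrityError(TroughVarError):
    """Cross-row consistency violation (duplicates, conflicting labels)."""


class InsufficientDataError(TroughVarError):
    """Not enough observations to compute the requested quantity."""


class ConfigurationError(TroughVarError):
    """Invalid parameter combination."""


class EmptyCohortError(TroughVarError):
    """An operation received a cohort with no trajectories."""
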