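"""Exception hierarchy shared across the package.

Every error carries enough provenance (field name, subject id, stage) for a
caller to report which input was at fault without re-deriving it.
"""


class PedmetsError(Exception):
    """Base class for all package errors."""


class DomainError(PedmetsError, ValueError):
    """An input value is outside the mathematical domain of an operation.

    ``field`` names the offending quantity (e.g. ``"height"``).
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class MissingDataError(PedmetsError, ValueError):
    """A required optional field (e.g. a DXA mass) is absent."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"required field is missing: {field}")


class CoverageError(PedmetsError, LookupError):
    """A reference table does not cover the requested (sex, age) point."""


class SchemaError(PedmetsError, ValueError):
    """A tabular input does not match the documented schema."""


class RowValidationError(PedmetsError, ValueError):
    """One or more data rows failed validation; ``errors`` lists them."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        summary = "; ".join(self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} invalid row(s): {summary}{more}")


class DegenerateInputError(PedmetsError, ValueError):
    """An analysis cannot run on this input (single class, empty group...)."""


class UnsupportedAgeError(PedmetsError, ValueError):
    """No diagnostic criteria set is defined for this age."""


class ConfigError(PedmetsError, ValueError):
    """Inconsistent or out-of-range configuration parameters."""


class PipelineStageError(PedmetsError, RuntimeError):
    """A pipeline stage failed; ``stage`` records where."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
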