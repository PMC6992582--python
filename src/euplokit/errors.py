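"""Exception hierarchy shared by all euplokit stages."""


class EuplokitError(Exception):
    """Base class for all package errors."""


class DomainError(EuplokitError):
    """An input is outside the mathematical domain of an operation."""


class ProfileError(EuplokitError):
    """A patient profile violates its invariants (e.g. age out of range)."""


class CoefficientError(EuplokitError):
    """A coefficient set is malformed or non-finite."""


class CohortSpecError(EuplokitError):
    """A simulator specification is internally inconsistent."""


class SchemaError(EuplokitError):
    """A CRF table violates the documented schema.

    Carries the offending row indices when they are known.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class SeparationError(EuplokitError):
    """The binomial likelihood is degenerate (complete separation)."""


class FitError(EuplokitError):
    """A model-fitting stage failed to produce a usable estimate."""


class StageError(EuplokitError):
    """A validation-pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
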