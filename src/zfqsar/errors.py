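"""Exception hierarchy shared across the pipeline stages."""


class ZfqsarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ZfqsarError):
    """A user file is missing a required column or is otherwise malformed."""


class TableParseError(ZfqsarError):
    """A cell in a user file could not be parsed; message names the row."""


class DegenerateCurveError(ZfqsarError):
    """Calibration curve with zero slope cannot be inverted."""


class DomainError(ZfqsarError):
    """A numeric argument is outside its physical domain."""


class InsufficientDataError(ZfqsarError):
    """Fewer data points than the operation requires."""


class SingularDesignError(ZfqsarError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class DegreesOfFreedomError(ZfqsarError):
    """No residual degrees of freedom left for the requested statistics."""


class LeverageError(ZfqsarError):
    """A leave-one-out leverage of 1 makes the deleted residual undefined."""


class OverParameterizedError(ZfqsarError):
    """Lack-of-fit penalty fraction reaches or exceeds 1."""


class LeakageError(ZfqsarError):
    """External test set overlaps the training compounds."""


class StructureError(ZfqsarError):
    """A molecular structure could not be parsed or sanitized."""


class ConformerError(ZfqsarError):
    """3D embedding failed for a compound."""


class JoinError(ZfqsarError):
    """Compound identifiers do not line up between two inputs."""


class EmptyMatrixError(ZfqsarError):
    """All descriptor columns were pruned away."""


class PoolError(ZfqsarError):
    """Descriptor pool too small for the requested subset sizes."""


class SpecError(ZfqsarError):
    """A synthetic-data specification is internally inconsistent."""


class PipelineError(ZfqsarError):
    """A pipeline stage failed; message names the stage and inputs."""
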