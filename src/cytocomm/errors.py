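"""Exception hierarchy for cytocomm.

All package-specific failures derive from :class:`CytocommError` so callers
can catch input/validation problems separately from programming errors.
"""


class CytocommError(Exception):
    """Base class for all cytocomm errors."""


class SchemaError(CytocommError):
    """A required column is missing from an input table."""


class ParseError(CytocommError):
    """A cell value could not be parsed as a number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyInputError(CytocommError):
    """An input file or group contained no data."""


class IncompleteSampleError(CytocommError):
    """A sample is missing one or more treatment conditions."""


class DuplicateKeyError(CytocommError):
    """A treatment index or sample key appears more than once."""


class PanelMismatchError(CytocommError):
    """Response matrices within one dataset use different channel panels."""


class OffsetViolationError(CytocommError):
    """A measurement lies below its transform offset (d - alpha < 0)."""


class InsufficientDataError(CytocommError):
    """Too few cells to fit the requested model."""


class DegenerateCovarianceError(CytocommError):
    """Covariance estimate is singular even after regularization."""


class DecompositionError(CytocommError):
    """A covariance matrix is not positive-definite."""


class UndefinedConditionalError(CytocommError):
    """A conditional probability is undefined because a class count is zero."""


class DegenerateNoiseError(CytocommError):
    """Total noise power is zero; SNR undefined."""


class DomainError(CytocommError):
    """An argument lies outside the mathematical domain of the operation."""


class InsufficientGroupError(CytocommError):
    """A comparison group has fewer than two members."""
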