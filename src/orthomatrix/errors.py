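"""Exception hierarchy shared across the pipeline stages."""


class OrthomatrixError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(OrthomatrixError, ValueError):
    """A configuration or operation parameter is outside its documented range."""


class MalformedRecordError(OrthomatrixError, ValueError):
    """A sequence record is internally inconsistent (e.g. base/quality length mismatch)."""


class EmptyInputError(OrthomatrixError, ValueError):
    """An operation that requires data received an empty collection."""


class InvalidAlignmentError(OrthomatrixError, ValueError):
    """Alignment rows are inconsistent (unequal lengths, broken codon frame)."""


class FrameInconsistencyError(InvalidAlignmentError):
    """A protein row does not translate from its coding sequence."""


class InvalidSymbolError(OrthomatrixError, ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class InvalidInputError(OrthomatrixError, ValueError):
    """Structurally invalid input (duplicate ids, mismatched leaf sets, ...)."""


class TooFewSequencesError(OrthomatrixError, ValueError):
    """A tree-building operation received fewer than three sequences."""


class UndefinedCoverageError(OrthomatrixError, ZeroDivisionError):
    """Coverage per base is undefined because the median target length is zero."""


class PipelineStageError(OrthomatrixError, RuntimeError):
    """An error raised while executing a named pipeline stage."""

    def __init__(self, stage: str, context: str, original: Exception):
        self.stage = stage
        self.context = context
        self.original = original
        super().__init__(f"stage {stage!r} failed for {context}: {original}")
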