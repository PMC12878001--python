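"""Exception hierarchy.

Every error raised by this package derives from :class:`RetrofictError`, so
callers driving bulk pipelines can catch one type, log the offending record,
and move on.
"""


class RetrofictError(Exception):
    """Base class for all package errors."""


class ReactionParseError(RetrofictError):
    """A reaction SMILES line could not be parsed into a valid record."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class MalformedRecordError(ReactionParseError):
    """Record parsed but violates a structural invariant (e.g. >1 product)."""


class RolePartitionError(RetrofictError):
    """Starting-material / reagent roles could not be assigned."""


class AmbiguousMappingError(RetrofictError):
    """Unmapped heavy atoms sit next to a bond change; centers undecidable."""


class NoReactionError(RetrofictError):
    """No atom changed between the two sides; nothing to extract."""


class TemplateExtractionError(RetrofictError):
    """Pattern generation failed for a reaction."""


class TaggingError(RetrofictError):
    """A changed-atom map number could not be located in the species."""


class TokenizationError(RetrofictError):
    """SMILES text could not be split into tokens (or rejoined)."""


class PredictorError(RetrofictError):
    """A predictor implementation failed on an input."""


class ContractError(RetrofictError):
    """An adapter-contract precondition was violated."""


class CheckpointError(RetrofictError):
    """Campaign checkpoint does not match the current configuration."""
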