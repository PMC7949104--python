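"""Exception hierarchy shared across the pipeline.

``ParseError`` marks malformed input files (with location where known);
``DataError`` marks structurally valid input that violates a precondition.
Both derive from ``ValueError`` so callers that do not care about the
distinction can catch the standard type.
"""


class PipelineError(ValueError):
    """Base class for all errors raised by trxmine."""


class ParseError(PipelineError):
    """A file could not be parsed; the message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DataError(PipelineError):
    """Input violates a documented precondition."""
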