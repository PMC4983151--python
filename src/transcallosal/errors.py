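"""Exception hierarchy.

``ValidationError`` (and subclasses) map to CLI exit code 2,
``FormatError`` and OS-level errors map to exit code 3.
"""


class TranscallosalError(Exception):
    """Base class for all package errors."""


class FormatError(TranscallosalError):
    """A file could not be parsed as the expected on-disk format."""


class TractogramParseError(FormatError):
    """Tractogram parsing failed; records the streamline index reached."""

    def __init__(self, message: str, streamline_index: int = 0):
        super().__init__(f"{message} (streamline index reached: {streamline_index})")
        self.streamline_index = streamline_index


class ValidationError(TranscallosalError):
    """Input data violates a documented precondition or invariant."""


class ParameterError(ValidationError):
    """An operation parameter is out of its documented domain."""


class ConfigurationError(ValidationError):
    """A configuration object is internally inconsistent or infeasible."""


class DegenerateInputError(ValidationError):
    """Input is degenerate for the requested operation (e.g. constant data)."""
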