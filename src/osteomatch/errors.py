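"""Exception hierarchy.

Input/format problems and computation problems are kept distinct so the
command line can map them to distinct exit codes.
"""


class OsteomatchError(Exception):
    """Base class for all package errors."""


class InputFormatError(OsteomatchError, ValueError):
    """A file or table did not conform to an expected layout."""


class LandmarkParseError(InputFormatError):
    """A coordinate token could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ComputationError(OsteomatchError, ValueError):
    """A numerical operation received degenerate or inconsistent input."""
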