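"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`MouseDiscoError`, so callers (and the CLI) can distinguish structured
analysis failures from programming errors.
"""


class MouseDiscoError(Exception):
    """Base class for all package errors."""


class AudioFormatError(MouseDiscoError):
    """The file is not a readable PCM WAV (unknown encoding, truncated, ...)."""


class EmptyInputError(MouseDiscoError):
    """Zero-length audio or an empty table where data is required."""


class InsufficientDataError(MouseDiscoError):
    """Not enough samples/frames/values for the requested analysis."""


class UndefinedStatisticError(MouseDiscoError):
    """The statistic is undefined for this input (e.g. all-zero spectrum)."""


class DegenerateDataError(MouseDiscoError):
    """A scale estimate collapsed to zero while the data still vary."""


class ParameterError(MouseDiscoError):
    """An argument is outside its documented domain."""
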