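"""Exception hierarchy."""


class TunnelprofError(Exception):
    """Base class for all package errors."""


class ParseError(TunnelprofError):
    """Malformed input file content."""


class TopologyError(TunnelprofError):
    """Snapshots of an ensemble disagree in atom count or ordering."""


class TypingError(TunnelprofError):
    """An atom could not be assigned a SYBYL type or parameter set."""


class PlacementError(TunnelprofError):
    """A substrate cannot be threaded at the requested anchor."""


class FormatError(TunnelprofError):
    """A value does not fit the fixed-width output format."""
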