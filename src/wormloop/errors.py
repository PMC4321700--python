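"""Exception hierarchy shared across the package."""


class WormloopError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WormloopError, ValueError):
    """A delimited-text input is structurally malformed (e.g. missing column)."""


class ParseError(WormloopError, ValueError):
    """A value in an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        super().__init__(message)


class ParameterError(WormloopError, ValueError):
    """An analysis parameter is out of its valid range."""


class TrackTooShortError(WormloopError, ValueError):
    """A trajectory's path length is below the requested analysis length L0."""

    def __init__(self, message: str, actual_length_mm: float):
        self.actual_length_mm = actual_length_mm
        super().__init__(message)


class DegenerateTrackError(WormloopError, ValueError):
    """Too few usable samples remain for path analysis (need >= 3)."""


class DegeneratePoseError(WormloopError, ValueError):
    """Head-pose landmarks coincide; the head angle is undefined."""


class InsufficientBleachError(WormloopError, ValueError):
    """Photobleaching removed too little signal for the rate-of-change formula."""
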