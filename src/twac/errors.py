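"""Exception hierarchy shared across the package."""


class TwacError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TwacError):
    """A file does not conform to the declared on-disk format."""


class UnitError(FormatError):
    """Amplitude calibration (gain/units) could not be interpreted."""


class RangeError(TwacError):
    """An index or window falls outside the signal it refers to."""


class WindowError(TwacError):
    """A search window is degenerate or does not fit inside the record."""


class InsufficientDataError(TwacError):
    """Too few beats (or leads) to compute the requested statistic."""


class CalibrationError(TwacError):
    """Threshold calibration is impossible on the given inputs."""


class EmptyOutputError(TwacError):
    """Asked to persist an empty result."""
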