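"""Exception hierarchy for the emgprofile pipeline.

All package errors derive from :class:`EmgProfileError` so callers can
distinguish pipeline failures from programming errors.
"""


class EmgProfileError(Exception):
    """Base class for all emgprofile errors."""


class ValidationError(EmgProfileError, ValueError):
    """Invalid argument or domain-object state."""


class ParseError(EmgProfileError, ValueError):
    """A delimited-text file could not be parsed as finite numbers."""


class InsufficientDurationError(ValidationError):
    """A recording is shorter than the analysis window it must support."""


class ResolutionError(ValidationError):
    """The envelope step is too coarse for the requested gap duration."""


class DegenerateCalibrationError(EmgProfileError):
    """Calibration produced a non-positive fMVC; normalization is impossible."""


class ModelFitError(EmgProfileError):
    """The ANOVA design is degenerate (empty or zero-variance cells)."""
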