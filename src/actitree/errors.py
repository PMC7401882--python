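"""Exception hierarchy shared across the package."""


class ActitreeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ActitreeError):
    """A file does not have the expected structure (column count, emptiness)."""


class ParseError(ActitreeError):
    """A row could not be parsed; the message names the offending line."""


class ValidationError(ActitreeError):
    """Input values violate a documented invariant."""


class ConfigurationError(ActitreeError):
    """An option or preset is unknown or inconsistent."""


class FrameError(ActitreeError):
    """A recording is in the wrong coordinate frame for the requested step."""


class TooShortError(ActitreeError):
    """A recording is shorter than one analysis window."""


class AlignmentError(ActitreeError):
    """Predictions and reference log do not overlap on a common time grid."""


class CalibrationError(ActitreeError):
    """A synthetic-signal target cannot be reached with the given parameters."""
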