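"""Exception hierarchy."""


class ContrastflowError(Exception):
    """Base class for all package errors."""


class ValidationError(ContrastflowError, ValueError):
    """An input value is outside its physiologically plausible range."""


class CalibrationError(ContrastflowError):
    """The attenuation model is uncalibrated or the anchor is inconsistent."""


class OutOfScopeError(ContrastflowError):
    """The requested case falls outside the modelled protocol family."""
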