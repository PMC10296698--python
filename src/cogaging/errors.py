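"""Exception types shared across the package."""


class CogagingError(Exception):
    """Base class for package errors."""


class ConfigError(CogagingError):
    """A configuration field is invalid; the message names the field."""


class InsufficientDataError(CogagingError):
    """Too few observations to perform the requested computation."""


class ValidationError(CogagingError):
    """An input table or vector violates its contract."""
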