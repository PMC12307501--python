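"""Exception types shared across the package."""


class AhagingError(Exception):
    """Base class for all package errors."""


class ValidationError(AhagingError, ValueError):
    """An input violates a documented invariant (duplicate ids, bad groups, ...)."""


class ParseError(AhagingError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ConfigurationError(AhagingError, ValueError):
    """A configuration value is outside its documented domain."""
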