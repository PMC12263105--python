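"""Exception hierarchy shared by all pipeline stages."""


class AopminerError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AopminerError):
    """A file does not conform to its declared external format."""


class ValidationError(AopminerError):
    """Well-formed input violates a domain invariant."""


class ConfigError(AopminerError):
    """A run or scoring configuration value is out of range."""
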