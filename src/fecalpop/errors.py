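"""Exception hierarchy used across the package."""


class FecalpopError(Exception):
    """Base class for all package errors."""


class ParseError(FecalpopError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FecalpopError):
    """An in-memory object violates one of its invariants."""


class ConfigError(FecalpopError):
    """A configuration value is out of range or inconsistent."""


class EstimationError(FecalpopError):
    """An estimator cannot be computed from the data provided."""
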