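"""Exception hierarchy shared across the package."""


class CircsyncError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(CircsyncError, ValueError):
    """A delimited input table does not match the declared layout."""


class TableParseError(CircsyncError, ValueError):
    """A cell in an input table could not be parsed as a number."""


class ValidationError(CircsyncError, ValueError):
    """A container invariant or an operation precondition is violated."""


class ConstantProfileError(ValidationError):
    """Pearson correlation requested for a zero-variance profile."""


class EmptyResultError(CircsyncError, ValueError):
    """A filtering step removed every gene."""


class ConfigError(CircsyncError, ValueError):
    """Invalid simulation or pipeline configuration."""
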