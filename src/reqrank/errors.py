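"""Exception hierarchy shared across the pipeline stages."""


class ReqrankError(Exception):
    """Base class for all package errors."""


class SchemaError(ReqrankError, ValueError):
    """A file or record does not match its documented schema."""


class IntegrityError(ReqrankError, ValueError):
    """Duplicate keys or cross-reference violations in otherwise valid data."""


class ShapeError(ReqrankError, ValueError):
    """A matrix-shaped input has the wrong dimensions."""


class CompletenessError(ReqrankError, ValueError):
    """A required cell or stage result is missing."""


class NumericError(ReqrankError, ArithmeticError):
    """A numerical routine failed (singular matrix, non-convergence, ...)."""


class ConfigurationError(ReqrankError, ValueError):
    """Invalid or incomplete run configuration."""
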