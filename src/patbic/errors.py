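"""Exception hierarchy shared across the package."""


class PatbicError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PatbicError):
    """Malformed input file (ragged rows, unparseable fields, ...)."""


class IdentifierError(PatbicError):
    """Duplicate or otherwise invalid row/column identifiers."""


class ConfigError(PatbicError):
    """Inconsistent or out-of-range parameter combination."""


class ValidationError(PatbicError):
    """Data that violates an operation's preconditions."""
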