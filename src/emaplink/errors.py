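"""Exception hierarchy shared across the package."""


class EMapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EMapError):
    """A file could not be parsed (malformed table, unparseable cell)."""


class ValidationError(EMapError):
    """A value or object violates an invariant (non-finite score, bad shape)."""


class SymmetryError(ValidationError):
    """An S-score table carries conflicting values above and below the diagonal."""

    def __init__(self, message: str, pairs=None):
        super().__init__(message)
        self.pairs = list(pairs) if pairs is not None else []


class ConfigurationError(EMapError):
    """Inconsistent or unusable analysis configuration (e.g. empty screen overlap)."""
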