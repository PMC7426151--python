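"""Exception hierarchy shared across the package."""


class DupliTdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DupliTdError):
    """A simulation or pipeline configuration failed validation."""


class InputError(DupliTdError):
    """An input value or file is malformed or out of range."""


class DesignError(DupliTdError):
    """The sample design does not support the requested contrast."""


class NormalizationError(DupliTdError):
    """Size factors cannot be computed (e.g. an all-zero sample)."""


class CatalogError(DupliTdError):
    """A duplicate-pair catalog is inconsistent."""


class ParseError(InputError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SaturationError(DupliTdError):
    """Synonymous divergence beyond the Jukes-Cantor correctable range."""
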