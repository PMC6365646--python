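"""Exception hierarchy shared across the package."""


class FitcallerError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FitcallerError, ValueError):
    """A numeric or categorical parameter is outside its allowed range."""


class ValidationError(FitcallerError, ValueError):
    """An input object violates a declared invariant (unknown label, bad index, ...)."""


class GenerationError(FitcallerError, RuntimeError):
    """Synthetic-data generation could not satisfy its postconditions."""


class FormatError(FitcallerError, ValueError):
    """A file does not conform to its declared tabular format.

    Carries a 1-based line number when the offending row is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConsistencyError(FitcallerError, ValueError):
    """Two inputs that must agree (counts vs metadata, ...) do not."""


class PairingError(FitcallerError, ValueError):
    """An experiment has no usable Time0 control."""


class DegenerateInputError(FitcallerError, ValueError):
    """An input is technically valid but unusable (e.g. zero-total sample)."""
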