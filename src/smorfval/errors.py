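"""Exception hierarchy used across the pipeline."""


class SmorfvalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SmorfvalError, ValueError):
    """Invalid simulation or analysis configuration."""


class GenerationError(SmorfvalError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class DataError(SmorfvalError, ValueError):
    """Malformed or incomplete input data (e.g. missing rate-table context)."""


class FormatError(SmorfvalError, ValueError):
    """Unparseable record in an input file; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class CoordinateError(SmorfvalError, ValueError):
    """Genomic coordinates outside the reference or entity bounds."""
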