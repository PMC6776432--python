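"""Exception hierarchy for qpcrval."""


class QpcrValError(Exception):
    """Base class for all qpcrval errors."""


class SchemaError(QpcrValError):
    """A required column is missing from an input table."""


class PlateParseError(QpcrValError):
    """A cell in a plate table could not be parsed; carries the 1-based row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class ConfigurationError(QpcrValError):
    """A config object is incomplete or inconsistent for the requested operation."""


class DegenerateFitError(QpcrValError):
    """A regression cannot be fit (single copy level, zero slope, ...)."""


class PairingError(QpcrValError):
    """A (target, standard) cell is missing one of the two paired conditions."""


class InsufficientDataError(QpcrValError):
    """Too few observations for the requested statistic."""
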