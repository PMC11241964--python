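"""Exception hierarchy for pvsignal."""


class PvSignalError(Exception):
    """Base class for all pvsignal errors."""


class FormatError(PvSignalError):
    """A file does not conform to the expected tabular dialect."""


class IntegrityError(PvSignalError):
    """Relational integrity of the line listing is violated."""


class ConfigError(PvSignalError):
    """A configuration value is invalid; the message names the offending key."""


class SeparationError(PvSignalError):
    """Complete or quasi-complete separation in a logistic model.

    The offending column is available as ``.column``.
    """

    def __init__(self, column: str, message: str | None = None):
        self.column = column
        super().__init__(message or f"separation detected for column {column!r}")


class ConvergenceError(PvSignalError):
    """The iterative fit did not converge within the iteration budget."""


class EstimateError(PvSignalError):
    """An estimate is undefined (e.g. zero cell with no correction)."""
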