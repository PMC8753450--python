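"""Exception hierarchy."""


class ClonodynError(Exception):
    """Base class for all package errors."""


class FormatError(ClonodynError):
    """A file does not conform to the expected tabular dialect."""


class RowParseError(ClonodynError):
    """A row failed to parse; carries the 1-based data row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class UndefinedStatisticError(ClonodynError):
    """A statistic is undefined on the given input (e.g. zero denominator)."""


class ConfigError(ClonodynError):
    """Invalid configuration or manifest."""


class FitError(ClonodynError):
    """A model fit could not be performed."""
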