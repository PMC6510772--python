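"""Exception hierarchy for the diallel package."""


class DiallelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DiallelError):
    """Input file is missing a required column or has a malformed header."""


class ParseError(DiallelError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ParentLabelError(DiallelError):
    """A parent label could not be mapped onto the 1..p index range."""


class DuplicateEntryError(DiallelError):
    """Two rows describe the same (environment, replicate, entry, trait) plot."""


class ImbalanceError(DiallelError):
    """The design is not fully balanced; lists the absent plot cells."""

    def __init__(self, message: str, missing: list[tuple] | None = None):
        super().__init__(message)
        self.missing = missing or []


class DesignTooSmallError(DiallelError):
    """Fewer parents than the estimators require (p < 3)."""


class AnalysisLookupError(DiallelError, KeyError):
    """Unknown environment or trait requested from a table."""


class ConfigError(DiallelError):
    """Invalid run or simulation configuration."""
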