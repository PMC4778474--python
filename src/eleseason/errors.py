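"""Exception hierarchy for the pipeline."""


class EleseasonError(Exception):
    """Base class for all package errors."""


class ConfigError(EleseasonError):
    """Invalid generator or pipeline configuration."""


class SchemaError(EleseasonError):
    """Input table missing required columns or containing bad values."""


class InsufficientDataError(EleseasonError):
    """Too few observations to compute the requested quantity."""


class DegenerateSeriesError(EleseasonError):
    """A series with zero variance (or otherwise unusable) was supplied."""


class MissingDataError(EleseasonError):
    """A required month or level is missing from the input."""
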