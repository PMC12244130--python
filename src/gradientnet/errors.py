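"""Exception hierarchy shared across the pipeline."""


class GradientNetError(Exception):
    """Base class for all pipeline errors."""


class TableFormatError(GradientNetError):
    """A required column or structural element is missing."""


class TableParseError(GradientNetError):
    """A cell could not be parsed; message carries the row number."""


class ValidationError(GradientNetError):
    """Parsed data violates a contract (duplicates, bad counts, ...)."""


class ConfigError(GradientNetError):
    """Invalid configuration value."""
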