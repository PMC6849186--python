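"""Exception hierarchy shared across the package."""


class ScreenflowError(Exception):
    """Base class for all errors raised by screenflow."""


class ConfigError(ScreenflowError):
    """Malformed or inconsistent analysis configuration."""


class ValidationError(ConfigError):
    """Config is syntactically fine but violates a schema constraint."""


class DataError(ScreenflowError):
    """Problem with an input table (missing column, bad cell, empty file)."""


class SchedulingError(ScreenflowError):
    """A triple's input place is neither produced nor present on disk."""
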