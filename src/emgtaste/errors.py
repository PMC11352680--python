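"""Labelled error types shared across the pipeline."""


class EmgTasteError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(EmgTasteError):
    """Invalid or inconsistent configuration."""


class SchemaError(EmgTasteError):
    """Malformed input file (missing columns, bad cells, wrong layout)."""


class StageOrderError(EmgTasteError):
    """A preprocessing stage was applied out of order."""


class FeatureUndefinedError(EmgTasteError):
    """A feature is mathematically undefined on this window (zero spectrum
    or zero time-domain variance); the window should be excluded."""


class EmptyDatasetError(EmgTasteError):
    """No samples survived to this stage."""
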