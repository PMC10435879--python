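"""Exception hierarchy for the pipeline."""


class LeukosigError(Exception):
    """Base class for all package errors."""


class ConfigError(LeukosigError):
    """An invalid configuration field; the message names the field."""


class SchemaError(LeukosigError):
    """An input table violates the expected schema."""


class StageError(LeukosigError):
    """A normalization stage was applied to a table in the wrong stage."""
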