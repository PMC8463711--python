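"""Exception types shared across the pipeline."""


class CitsciBiasError(Exception):
    """Base class for all package errors."""


class SchemaError(CitsciBiasError):
    """An input table is missing a required column or has an unusable dtype."""


class EmptyInputError(CitsciBiasError):
    """An input file or table contained no data rows."""


class ConfigError(CitsciBiasError):
    """A configuration value is invalid; the message names the field."""
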