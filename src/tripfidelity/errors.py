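"""Exception types shared across the pipeline."""


class SchemaError(ValueError):
    """An input table is missing a required column or has an invalid value."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or refers to an unknown entity."""
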