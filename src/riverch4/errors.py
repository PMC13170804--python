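"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Raised when a configuration (params, lookup table, config file) is
    inconsistent or incomplete, as opposed to a runtime data problem."""
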