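"""Exception types shared across pipeline stages."""


class ConfigurationError(ValueError):
    """A parameter or configuration value is invalid or unusable."""


class InputError(ValueError):
    """A data input (volume, mask, label set) violates a precondition."""
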