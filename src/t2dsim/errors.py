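"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration file or parameter table is invalid or incomplete."""


class StateError(RuntimeError):
    """An operation was applied to a patient in an inapplicable health state."""
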