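"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid generator or analysis configuration (bands, rates, durations)."""


class InsufficientDataError(ValueError):
    """Not enough samples, spikes, or epochs to compute the requested quantity."""
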