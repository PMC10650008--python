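"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter violates a precondition (bad band edges, singular optics, ...)."""


class DataError(ValueError):
    """The data violate a contract (non-positive intensity, schedule overrun, ...)."""
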