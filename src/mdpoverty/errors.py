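"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class MissingDataError(ValueError):
    """A required survey field is absent or null; nothing is silently imputed."""


class ValidationError(ValueError):
    """An input violates a structural precondition (shape, weights, emptiness)."""
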