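"""Exception types shared across enkit modules."""


class EnkitError(Exception):
    """Base class for all enkit errors."""


class DimensionError(EnkitError, ValueError):
    """Array shapes or lengths are inconsistent with each other."""


class ConfigurationError(EnkitError, ValueError):
    """A parameter or spec value is outside its legal domain."""


class SignalValidationError(EnkitError, ValueError):
    """Input signal violates an invariant (e.g. non-finite values)."""
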