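"""Package-wide exception types."""


class AcucoderError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AcucoderError, ValueError):
    """An invalid configuration value or combination."""


class SchemaError(AcucoderError, ValueError):
    """Data that does not conform to its declared schema."""


class NotFittedError(AcucoderError, RuntimeError):
    """A model was used before it was fitted."""
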