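"""Package-specific exception types."""


class BafawubuError(Exception):
    """Base class for package errors."""


class InsufficientDataError(BafawubuError):
    """A stream or dataset is too short for the requested operation."""


class ConfigurationError(BafawubuError):
    """A model or pipeline configuration is invalid."""
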