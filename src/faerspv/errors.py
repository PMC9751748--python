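"""Exception taxonomy shared across the package."""


class FaersPvError(Exception):
    """Base class for all package-specific errors."""


class InputError(FaersPvError):
    """A required input file or directory is missing or unreadable."""


class SchemaError(FaersPvError):
    """An input table header lacks a required column."""


class DictionaryError(FaersPvError):
    """A drug or PT->SOC dictionary violates its invariants."""


class ConfigurationError(FaersPvError):
    """A run configuration (thresholds, generator settings, ...) is invalid."""


class ParameterError(FaersPvError, ValueError):
    """A function argument is out of its documented domain."""
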