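"""Exception hierarchy shared across the package."""


class BiomodulesError(Exception):
    """Base class for all package errors."""


class ConfigError(BiomodulesError):
    """Invalid run configuration (missing inputs, bad parameter values)."""


class DataError(BiomodulesError):
    """Invalid data content."""


class FormatError(DataError):
    """A file could not be parsed in the named dialect."""


class ValidationError(DataError):
    """Parsed data violates a structural invariant."""
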