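"""Exception hierarchy shared by all modules."""


class OtuTopicsError(Exception):
    """Base class for all package errors."""


class ParseError(OtuTopicsError):
    """A delimited input file could not be parsed into a count table."""


class ValidationError(OtuTopicsError):
    """An in-memory object violates a structural contract."""


class ConfigError(OtuTopicsError):
    """A run configuration or operation setting is invalid."""
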