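"""Exception hierarchy shared across the pipeline stages."""


class IpmsnetError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(IpmsnetError):
    """A configuration value is invalid; the message names the offending field."""


class SchemaError(IpmsnetError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(IpmsnetError):
    """Input content violates a contract (duplicate keys, negative abundances, ...)."""
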