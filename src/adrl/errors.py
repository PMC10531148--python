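"""Exception hierarchy shared across the pipeline."""


class AdrlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdrlError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(AdrlError, ValueError):
    """A numeric argument outside its mathematical domain (e.g. gamma >= 1)."""


class DataError(AdrlError, ValueError):
    """Input data that violate a precondition (missing feature, bad support)."""
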