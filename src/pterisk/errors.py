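"""Exception hierarchy shared across the package."""


class PteriskError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PteriskError, ValueError):
    """An input violates a documented precondition (negative dose, empty collection, ...)."""


class ConfigError(PteriskError, ValueError):
    """An invalid configuration value (unknown mode, bad distribution family, ...)."""


class NoReferenceValue(PteriskError, LookupError):
    """No reference dose / reference concentration exists for the requested element and route."""


class NoSlopeFactor(PteriskError, LookupError):
    """No cancer slope factor exists for the requested element and route (non-carcinogen)."""


class NotTestable(PteriskError, ValueError):
    """A statistical test cannot be run on the available data (too few uncensored values)."""


class InputFormatError(PteriskError, ValueError):
    """A tabular input file failed validation; message carries the offending row number."""
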