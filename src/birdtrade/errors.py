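"""Exception hierarchy shared across the pipeline stages."""


class BirdTradeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BirdTradeError):
    """An invalid configuration value (synthetic world or pipeline)."""


class FormatError(BirdTradeError):
    """A malformed input file (missing columns, bad header)."""


class DataError(BirdTradeError):
    """Inconsistent data content (duplicate keys, non-finite covariates)."""


class DegenerateBinningError(BirdTradeError):
    """Too few distinct values to form quintile bins."""


class DomainError(BirdTradeError):
    """A value outside the mathematical domain of an operation."""
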