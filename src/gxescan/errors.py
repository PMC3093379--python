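"""Exception hierarchy shared across the package."""


class GxescanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GxescanError, ValueError):
    """Invalid or inconsistent scenario/analysis configuration."""


class DataError(GxescanError, ValueError):
    """Input data violates a documented invariant (shapes, ranges, schema)."""


class ParseError(DataError):
    """A genotype/phenotype file could not be parsed."""


class NotSupportedError(GxescanError, ValueError):
    """Operation requested for a family/setting it is not defined for."""
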