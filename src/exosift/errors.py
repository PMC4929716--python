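"""Exception hierarchy for exosift."""


class ExosiftError(Exception):
    """Base class for all exosift errors."""


class SchemaError(ExosiftError):
    """Header row cannot be resolved to the canonical column roles."""


class FormatError(ExosiftError):
    """A data row or file violates the expected tab-delimited layout."""


class ConfigError(ExosiftError):
    """Invalid filter configuration or preset name."""


class StratumError(ExosiftError):
    """A synthetic stratum specification is inconsistent or ambiguous."""
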