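"""Exception hierarchy shared across the package."""


class BioregionsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BioregionsError, ValueError):
    """Invalid configuration (rates out of range, zero counts, bad thresholds)."""


class SchemaError(BioregionsError, ValueError):
    """Input table is missing required columns or has an unusable layout."""


class NameParseError(BioregionsError, ValueError):
    """A taxon name could not be parsed into genus / epithet / qualifier."""


class ContractViolation(BioregionsError, ValueError):
    """An operation received input that an upstream stage should have ruled out."""
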