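"""Exception hierarchy for the ivmr package."""


class IvmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IvmrError):
    """A configuration value or column mapping is unusable."""


class ValidationError(IvmrError):
    """Input data violates a domain invariant (bad rows, duplicates...)."""


class HarmonizationError(IvmrError):
    """Exposure and outcome share no variants, or harmonization is impossible."""


class DegenerateInstrumentError(IvmrError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class InsufficientInstrumentsError(IvmrError):
    """An estimator was called with fewer instruments than it requires."""
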