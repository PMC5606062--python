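"""Exception hierarchy for mrkit."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A config file, dialect, or parameter set is invalid (e.g. missing column)."""


class ValidationError(MRKitError):
    """Input data violate a structural invariant (e.g. duplicate SNP ids)."""


class InsufficientInstrumentsError(MRKitError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(MRKitError):
    """Wald ratio requested for a SNP with zero exposure effect."""
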