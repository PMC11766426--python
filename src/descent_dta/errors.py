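"""Exception hierarchy shared across the analysis stages."""


class DescentDTAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DescentDTAError):
    """Invalid configuration values (probabilities outside [0,1], negative SDs, ...)."""


class SchemaError(DescentDTAError):
    """Input table does not match the expected schema."""


class InsufficientDataError(DescentDTAError):
    """Too few complete observations for the requested statistic."""


class DegenerateInputError(DescentDTAError):
    """Input has no variation where the statistic requires some (zero variance, one class)."""
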