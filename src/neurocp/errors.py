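"""Exception hierarchy for the change-point analysis pipeline."""


class NeurocpError(Exception):
    """Base class for all package errors."""


class SchemaError(NeurocpError):
    """An input table is missing required columns."""


class ValidationError(NeurocpError):
    """An input table violates a data-model invariant (duplicates, bad codes...)."""


class ParseError(NeurocpError):
    """A cell could not be converted to the expected type; message carries the row."""


class InsufficientDataError(NeurocpError):
    """Too few observations to fit the requested model."""


class ConfigurationError(NeurocpError):
    """A configuration value is invalid or produces an empty search space."""


class RankDeficiencyError(NeurocpError):
    """The design matrix is rank deficient at the requested change-point."""


class NoFitError(NeurocpError):
    """No candidate change-point admitted an identifiable fit."""


class UnstableBootstrapError(NeurocpError):
    """More than half of the bootstrap resamples failed to produce an estimate."""
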