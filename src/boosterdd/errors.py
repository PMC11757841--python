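"""Exception hierarchy shared by the pipeline modules."""


class BoosterDDError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BoosterDDError, ValueError):
    """A task or run configuration violates its invariants."""


class StateError(BoosterDDError, RuntimeError):
    """An operation was applied to a titration state that cannot accept it."""


class ProtocolError(BoosterDDError, TypeError):
    """A responder returned something outside the choice protocol."""


class DomainError(BoosterDDError, ValueError):
    """Input values fall outside the mathematical domain of an operation."""


class ValidationError(BoosterDDError, ValueError):
    """Tabular or questionnaire input failed validation."""


class DegenerateInputError(BoosterDDError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class FitError(BoosterDDError, RuntimeError):
    """A model fit failed to converge or produced a non-finite optimum."""


class UsageError(BoosterDDError, ValueError):
    """Operations combined in a statistically invalid way (e.g. non-nested LRT)."""
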