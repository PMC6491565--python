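"""Exception hierarchy for cohort validation and model configuration."""


class GroupNetError(Exception):
    """Base class for all package errors."""


class SchemaError(GroupNetError, ValueError):
    """A cohort file or config does not match the expected schema."""


class ValidationError(GroupNetError, ValueError):
    """Data fails an invariant (non-binary label, out-of-range class...)."""


class ConfigError(GroupNetError, ValueError):
    """An architecture or training configuration is internally inconsistent."""


class InfeasibleCorrelationError(GroupNetError, ValueError):
    """A target phi coefficient is unreachable for the given prevalences.

    Carries the feasible interval so callers can report it.
    """

    def __init__(self, message: str, feasible: tuple[float, float]):
        super().__init__(message)
        self.feasible = feasible
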