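"""Exception hierarchy for venpk."""


class VenpkError(Exception):
    """Base class for all venpk errors."""


class ValidationError(VenpkError):
    """Input data or arguments violate a documented contract."""


class SchemaError(ValidationError):
    """A dataset file does not match the declared column schema."""


class InvalidParameterError(ValidationError):
    """A structural or statistical parameter is out of its admissible range."""


class ConfigurationError(VenpkError):
    """A run or dataset configuration is incomplete or inconsistent."""


class NumericalError(VenpkError):
    """A numerical routine failed (integrator breakdown, underflow, ...)."""


class ConvergenceError(VenpkError):
    """An optimisation did not reach its convergence criterion."""
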