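"""Exception hierarchy shared across the audit pipeline."""


class MetabiasError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MetabiasError, ValueError):
    """A value violates a domain invariant (nonpositive bound, bad enum, ...)."""


class SchemaError(InvalidInputError):
    """An input file does not match the documented column schema."""


class InsufficientStudiesError(InvalidInputError):
    """Too few primary studies for the requested statistic."""


class DegenerateDesignError(InvalidInputError):
    """The regression design is singular (e.g. all standard errors identical)."""


class SimulationExhaustedError(MetabiasError, RuntimeError):
    """Selective publication too severe to reach the target study count."""
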