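"""Exception types shared across the package."""


class QuailThermError(Exception):
    """Base class for all package errors."""


class SchemaError(QuailThermError):
    """An input table is missing required columns or has the wrong dialect."""


class ValidationError(QuailThermError):
    """A row or record violates a domain invariant."""


class ConfigurationError(QuailThermError):
    """An option, mapping, or specification entry is unknown or inconsistent."""


class InputError(QuailThermError):
    """A numeric input violates a precondition (e.g. trace too short)."""


class SpecificationError(QuailThermError):
    """A Bayesian model is incompletely or inconsistently specified."""


class SamplingError(QuailThermError):
    """Posterior sampling failed (ill-posed model, non-finite density)."""


class UnidentifiableModelError(QuailThermError):
    """The data cannot identify the requested model (e.g. one temperature)."""
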