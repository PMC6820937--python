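"""Exception hierarchy shared across the package."""


class GlyGfrError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GlyGfrError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InputError(GlyGfrError, ValueError):
    """Structurally invalid input (missing field, unknown code, bad name)."""


class ValidationError(GlyGfrError, ValueError):
    """A data table or serialized object violates its invariants."""


class FitError(GlyGfrError, RuntimeError):
    """A model fit could not be carried out (singularity, under-filled stratum)."""


class GenerationError(GlyGfrError, RuntimeError):
    """The cohort simulator could not satisfy its configuration."""
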