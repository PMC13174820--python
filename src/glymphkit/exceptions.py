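"""Exception hierarchy shared across glymphkit modules."""


class GlymphkitError(Exception):
    """Base class for all package errors."""


class InvalidModelError(GlymphkitError):
    """Model parameters violate an invariant (non-PSD tensor, f outside [0, 1])."""


class InsufficientDataError(GlymphkitError):
    """Acquisition cannot identify the requested model (e.g. single nonzero shell)."""


class DegenerateTensorError(GlymphkitError):
    """Tensor eigenvalues are negative beyond tolerance."""


class InputError(GlymphkitError):
    """Inconsistent or malformed user input (shape mismatch, unknown preset...)."""
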