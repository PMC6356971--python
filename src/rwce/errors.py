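"""Exception types shared across the package."""


class RWCEError(Exception):
    """Base class for package-specific errors."""


class ParameterError(RWCEError, ValueError):
    """A parameter is outside its documented domain."""


class EnsembleStructureError(RWCEError, ValueError):
    """An ensemble or pooled membership matrix violates a structural invariant."""


class ConvergenceError(RWCEError, RuntimeError):
    """An iterative solver exhausted its iteration budget.

    Carries the final residual so callers can decide whether to retry with a
    looser tolerance or a larger budget.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class IsolatedInstanceError(RWCEError, ValueError):
    """An instance vertex has zero total association weight (degree 0)."""


class ViewAlignmentError(RWCEError, ValueError):
    """Instance identifiers differ across data views that must be matched."""
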