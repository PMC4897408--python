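"""Exception types raised across the package."""


class NHPMError(Exception):
    """Base class for all package-specific errors."""


class InvalidOrderError(NHPMError, ValueError):
    """A fractional order outside its admissible range."""


class LatticeViolationError(NHPMError, ValueError):
    """An operation would produce a t-exponent off the {n*alpha} lattice."""


class AlphaMismatchError(NHPMError, ValueError):
    """Two series with different fractional orders were combined."""


class InconsistencyError(NHPMError, RuntimeError):
    """Canonical simplification and numeric probing disagree about zero-ness."""


class UnsupportedModelError(NHPMError, ValueError):
    """The model lies outside the class the solver handles."""


class SolveFailureError(NHPMError, RuntimeError):
    """A coefficient equation could not be solved; carries the order index."""

    def __init__(self, message: str, order: int | None = None):
        super().__init__(message)
        self.order = order


class ConvergenceError(NHPMError, RuntimeError):
    """A numeric series summation failed to reach the requested tolerance."""

    def __init__(self, message: str, terms_used: int | None = None):
        super().__init__(message)
        self.terms_used = terms_used


class DomainError(NHPMError, ValueError):
    """Numeric evaluation requested outside the declared domain."""
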