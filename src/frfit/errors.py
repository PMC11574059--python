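"""Exception hierarchy for functional-response fitting and analysis."""


class FRFitError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(FRFitError, ValueError):
    """A model parameter is outside its admissible domain (a < 0, h < 0, T <= 0, ...)."""


class ConvergenceError(FRFitError, RuntimeError):
    """An iterative solver or optimizer failed to converge.

    Carries diagnostic context (residual, best candidate, gradient norm)
    in ``details`` when available.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class DegenerateDataError(FRFitError, ValueError):
    """The data cannot identify the model (single density, all-zero feeding,
    complete separation in the type test, ...)."""


class BootstrapInstabilityError(FRFitError, RuntimeError):
    """Too large a fraction of bootstrap replicate fits failed."""

    def __init__(self, message: str, n_failed: int, n_boot: int):
        super().__init__(message)
        self.n_failed = n_failed
        self.n_boot = n_boot


class TrialValidationError(FRFitError, ValueError):
    """A trial table violates the documented dialect; ``offenses`` lists
    (line_number, message) pairs for the first failures found."""

    def __init__(self, message: str, offenses: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.offenses = offenses or []
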