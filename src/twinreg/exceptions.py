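"""Exception types shared across the package."""


class TwinregError(Exception):
    """Base class for all twinreg errors."""


class StructuralViolationError(TwinregError):
    """A value was supplied for a cell that the factor pattern fixes to zero."""


class NotPositiveDefiniteError(TwinregError):
    """A covariance matrix required to be positive definite is not."""


class RankDeficiencyError(TwinregError):
    """A predictor covariance block is singular or too ill-conditioned to invert.

    Carries the offending eigenvalues so callers can see how close to
    singular the block is.
    """

    def __init__(self, message: str, eigenvalues=None):
        super().__init__(message)
        self.eigenvalues = eigenvalues


class DataError(TwinregError):
    """Malformed or degenerate input data."""


class ConvergenceError(TwinregError):
    """An optimization failed in a way that cannot be reported as a flagged result."""
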