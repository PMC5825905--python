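"""Exception hierarchy for regplsc.

All errors raised by the library derive from :class:`RegPLSError` so callers
can catch the whole family with one clause.
"""


class RegPLSError(Exception):
    """Base class for all regplsc errors."""


class SpecError(RegPLSError):
    """Invalid model specification (blocks, paths, correlations, columns)."""


class InvalidPopulationError(RegPLSError):
    """A population implied by the requested parameters does not exist
    (e.g. structural coefficients explain >= 100% of a latent variance,
    or the implied indicator covariance is not positive definite)."""


class DegenerateDataError(RegPLSError):
    """Data unusable for estimation (zero-variance column, NaNs, too few rows)."""


class ConvergenceError(RegPLSError):
    """The iterative weight algorithm did not converge within ``max_iter``.

    Carries the last iterate in :attr:`last_weights`.
    """

    def __init__(self, message, last_weights=None, n_iter=None):
        super().__init__(message)
        self.last_weights = last_weights
        self.n_iter = n_iter


class UndefinedReliabilityError(RegPLSError):
    """rho_A is undefined for the supplied weights (single effective indicator)."""


class SingularMatrixError(RegPLSError):
    """A (consistent) correlation matrix is singular or not positive definite.

    Carries the smallest eigenvalue when known.
    """

    def __init__(self, message, smallest_eigenvalue=None):
        super().__init__(message)
        self.smallest_eigenvalue = smallest_eigenvalue


class FoldSizeError(RegPLSError):
    """A cross-validation fold is too small to estimate on."""


class UnstableInferenceError(RegPLSError):
    """More than half of the bootstrap resamples failed to produce estimates."""


class ConfigError(RegPLSError):
    """Invalid run configuration (missing fields, bad levels, zero replications)."""
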