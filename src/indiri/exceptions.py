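"""Exception hierarchy shared across the toolkit."""


class IndiriError(Exception):
    """Base class for all toolkit errors."""


class DomainError(IndiriError, ValueError):
    """Input outside the mathematical domain of an operation."""


class InsufficientDataError(IndiriError, ValueError):
    """Too few observations for the requested operation."""


class SingularDesignError(IndiriError, ValueError):
    """Regression design matrix is singular (e.g. a constant predictor)."""


class UnbalancedDesignError(IndiriError, ValueError):
    """A required factor-level cell is empty."""


class UnbalanceableError(IndiriError, ValueError):
    """Stratified balancing cannot be performed; names the offending cell."""


class DegenerateVarianceError(IndiriError, ValueError):
    """A variance that must be positive is (numerically) zero."""


class ConvergenceError(IndiriError, RuntimeError):
    """An iterative fit failed to converge in all attempts."""


class CollapseError(IndiriError, RuntimeError):
    """A mixture component collapsed onto a point mass."""


class NonMonotoneError(IndiriError, ValueError):
    """A fitted region has non-positive slope where positive is required."""


class InvalidCurvatureError(IndiriError, ValueError):
    """Log-histogram slope has the wrong sign for a Gaussian component."""


class GapError(IndiriError, ValueError):
    """Zero-count bin inside a candidate histogram region."""


class SearchError(IndiriError, RuntimeError):
    """Parameter search failed; message reports the best candidate so far."""


class UnstableEstimatorError(IndiriError, RuntimeError):
    """Estimator failed on too large a fraction of bootstrap resamples."""


class InvalidReferenceError(IndiriError, ValueError):
    """Reference interval used as a standard is ill-formed."""


class FormatError(IndiriError, ValueError):
    """Input file does not match the expected layout."""
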