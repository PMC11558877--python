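"""Exception and warning types used across the package."""


class SmallGeeError(Exception):
    """Base class for all package-specific errors."""


class DataError(SmallGeeError):
    """Malformed input data (non-binary outcome, missing columns, bad ordering)."""


class OccasionCollisionError(DataError):
    """Duplicate occasion label within a single cluster."""


class OrderingError(DataError):
    """Cluster rows are not contiguous and no occasion column was supplied."""


class SpecificationError(SmallGeeError):
    """Invalid model specification (missing term column, degenerate factor)."""


class ParameterRangeError(SmallGeeError):
    """Correlation parameter outside its admissible range."""


class InsufficientDataError(SmallGeeError):
    """Not enough observations or residual pairs for a moment estimator."""


class StructureInfeasibleError(InsufficientDataError):
    """Requested correlation structure cannot be identified from the data."""


class NumericalError(SmallGeeError):
    """Linear-algebra failure (singular matrix, non-PD correlation, bad root)."""


class SingularDesignError(NumericalError):
    """Design matrix is rank deficient."""


class FeasibilityError(SmallGeeError):
    """Requested binary correlation is outside the Frechet-compatible range."""


class ConvergenceWarning(UserWarning):
    """Iterative fit stopped without meeting the convergence tolerance."""


class SeparationWarning(UserWarning):
    """Coefficients drifting to extreme values; data may be separated."""


class ClampingWarning(UserWarning):
    """A moment estimate of a correlation parameter was clamped into range."""


class CovarianceWarning(UserWarning):
    """A covariance estimate is indefinite or otherwise suspect."""
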