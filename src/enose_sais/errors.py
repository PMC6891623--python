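"""Exception hierarchy shared across the package."""


class EnoseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EnoseError, ValueError):
    """A parameter is outside its valid range (e.g. cutoff at/above Nyquist)."""


class DataError(EnoseError, ValueError):
    """Input data violates a precondition (non-finite values, bad labels, ...)."""


class DegenerateFeatureError(DataError):
    """A feature column has zero variance and cannot be z-scored."""


class ShapeMismatchError(EnoseError, ValueError):
    """Matrix/vector dimensions are incompatible."""


class RankError(EnoseError, ValueError):
    """Requested subspace size exceeds the effective rank of the data.

    Attributes
    ----------
    achievable : int
        Largest subspace size the data supports.
    """

    def __init__(self, message: str, achievable: int):
        super().__init__(message)
        self.achievable = achievable


class GenerationError(EnoseError, RuntimeError):
    """Synthetic-data generation failed (e.g. class separation infeasible)."""
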