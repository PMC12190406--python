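"""Exception hierarchy shared across the package."""


class CuemedError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CuemedError):
    """A spec/config object violates its invariants."""


class DegenerateDesignError(CuemedError):
    """Design has no usable variation (e.g. all stimulus magnitudes identical)."""


class InsufficientDataError(CuemedError):
    """Fewer usable observations than the operation requires."""


class NonInvertibleCalibrationError(CuemedError):
    """Calibration slope is non-positive; targets cannot be inverted."""


class EstimabilityError(CuemedError):
    """Design matrix is rank deficient; offending columns are named."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


class SingularFitError(CuemedError):
    """A per-subject regression cannot be fit (constant predictor or mediator)."""


class GridMismatchError(CuemedError):
    """Two voxel images do not share a grid; resampling is out of scope."""
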