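"""Exception hierarchy.

Every contract violation raises a distinct subclass of :class:`NormMapError`
so callers (and the CLI) can react to specific failure modes instead of
pattern-matching on messages.
"""


class NormMapError(Exception):
    """Base class for all package errors."""


class VolumeReadError(NormMapError):
    """The file could not be read as a NIfTI-1 image."""


class DimensionalityError(NormMapError):
    """The image is not a 3D scalar volume."""


class NonFiniteDataError(NormMapError):
    """The volume contains NaN or infinite voxels."""


class NegativeDataError(NormMapError):
    """The volume contains negative gray-matter values."""


class GridMismatchError(NormMapError):
    """Two volumes/masks do not live on the same voxel grid."""


class CohortTableError(NormMapError):
    """Malformed cohort metadata table."""


class MissingColumnError(CohortTableError):
    """A required CSV column is absent."""


class DuplicateSubjectError(CohortTableError):
    """The same subject_id appears more than once."""


class InvalidFieldError(CohortTableError):
    """A cell could not be parsed (age, sex, ...)."""


class EmptyMaskError(NormMapError):
    """A brain/region mask selects no voxels."""


class TooFewSubjectsError(NormMapError):
    """Fewer volumes than the operation requires (templates need >= 2)."""


class PoolTooSmallError(NormMapError):
    """The matched normal pool is smaller than required.

    Carries ``required`` and ``available`` so the shortfall can be reported.
    """

    def __init__(self, message, required=None, available=None):
        super().__init__(message)
        self.required = required
        self.available = available


class EmptyCurveError(NormMapError):
    """A consistency curve with no points was passed where data is required."""


class KneeInputError(NormMapError):
    """Knee detection input malformed (too few points, non-increasing x)."""
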