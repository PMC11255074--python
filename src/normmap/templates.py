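"""Age/sex-specific normal templates and z-score atrophy maps.

The normative-mapping core: healthy subjects of the same sex within an age
window of the patient form the matched pool; a *normal template* is the
voxel-wise mean and SD over a set of matched volumes; a patient's *atrophy
map* is the voxel-wise z-score against that template,

    z = (patient - mean) / sd   wherever sd > epsilon.

Strongly negative z indicates gray-matter volume loss relative to the
matched normal cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DuplicateSubjectError,
    GridMismatchError,
    NormMapError,
    TooFewSubjectsError,
)
from .grid import BrainMask, GMVolume, VoxelGrid, require_same_grid
from .io import SubjectRecord

#: voxels with template SD at or below this are flagged invalid in z-maps
DEFAULT_EPSILON = 1e-6

#: default half-width of the age window for matching, in years
DEFAULT_AGE_WINDOW = 2

#: brain-mask policy: template-mean threshold as a fraction of its maximum
DEFAULT_MASK_FRACTION = 0.05


@dataclass
class NormalTemplate:
    """Voxel-wise mean/SD over a matched set of healthy subjects."""

    grid: VoxelGrid
    mean: np.ndarray
    sd: np.ndarray
    subject_ids: list[str]
    sex: str = ""
    age_center: int | None = None
    age_window: int = DEFAULT_AGE_WINDOW
    #: SD denominator convention: 1 -> sample SD (n-1), 0 -> population SD
    ddof: int = 1

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.mean.shape != self.grid.shape or self.sd.shape != self.grid.shape:
            raise GridMismatchError("template mean/sd shape does not match grid")
        if (self.sd < 0).any():
            raise NormMapError("template SD must be nonnegative")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DuplicateSubjectError("template subject_ids are not unique")
        if len(self.subject_ids) < 2:
            raise TooFewSubjectsError("a template needs at least 2 subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class ZMap:
    """Voxel-wise z-scores of one patient against a normal template."""

    grid: VoxelGrid
    z: np.ndarray
    valid: np.ndarray
    patient_id: str = ""
    template_ref: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.z.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise GridMismatchError("z/valid shape does not match grid")
        if not np.isfinite(self.z[self.valid]).all():
            raise NormMapError("z-map contains non-finite values at valid voxels")


def match_subjects(
    cohort: list[SubjectRecord],
    age: int,
    sex: str,
    age_window: int = DEFAULT_AGE_WINDOW,
) -> list[SubjectRecord]:
    """Records of the same sex with |record.age - age| <= age_window.

    Bounds are inclusive and input order is preserved. An empty result is
    valid (the caller decides whether the pool is big enough).
    """
    return [
        r
        for r in cohort
        if r.sex == sex and abs(r.age - age) <= age_window
    ]


def build_template(
    volumes: list[GMVolume],
    sex: str = "",
    age_center: int | None = None,
    age_window: int = DEFAULT_AGE_WINDOW,
    ddof: int = 1,
) -> NormalTemplate:
    """Voxel-wise mean and SD over >= 2 matched volumes on one grid.

    The SD uses the sample (n-1) denominator by default; ``ddof=0`` selects
    the population convention. Each subject may appear only once.

    Volumes are canonically ordered by subject_id before accumulation, so the
    template is a function of the subject *set*: two draws of the same
    subjects yield bit-identical mean/SD regardless of draw order.
    """
    if len(volumes) < 2:
        raise TooFewSubjectsError(
            f"need >= 2 volumes to build a template, got {len(volumes)}"
        )
    ids = [v.subject_id for v in volumes]
    if len(set(ids)) != len(ids):
        raise DuplicateSubjectError("duplicate subject in template volumes")
    volumes = sorted(volumes, key=lambda v: v.subject_id)
    ids = [v.subject_id for v in volumes]
    first = volumes[0]
    for v in volumes[1:]:
        require_same_grid(first, v, "template volumes")
    stack = np.stack([v.values for v in volumes])
    return NormalTemplate(
        grid=first.grid,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=ddof),
        subject_ids=ids,
        sex=sex,
        age_center=age_center,
        age_window=age_window,
        ddof=ddof,
    )


def compute_zmap(
    patient: GMVolume,
    template: NormalTemplate,
    epsilon: float = DEFAULT_EPSILON,
) -> ZMap:
    """Voxel-wise z-scores of a patient volume against a template.

    Voxels with template SD <= epsilon are marked invalid and carry z = 0
    (never an infinity); downstream spatial statistics must respect the
    validity mask.
    """
    if epsilon <= 0:
        raise NormMapError(f"epsilon must be > 0, got {epsilon}")
    if tuple(patient.values.shape) != template.grid.shape or not (
        patient.grid.compatible_with(template.grid)
    ):
        raise GridMismatchError("patient and template grids differ")
    valid = template.sd > epsilon
    z = np.zeros(template.grid.shape, dtype=np.float64)
    np.divide(patient.values - template.mean, template.sd, out=z, where=valid)
    return ZMap(
        grid=template.grid,
        z=z,
        valid=valid,
        patient_id=patient.subject_id,
        template_ref=f"n={template.n_subjects}",
    )


def brain_mask_from_template(
    template: NormalTemplate,
    fraction: float = DEFAULT_MASK_FRACTION,
) -> BrainMask:
    """Support for spatial statistics: voxels where the template mean exceeds
    ``fraction`` of its global maximum. A crude but robust brain/background
    separation for modulated GM maps, configurable to an explicit mask."""
    threshold = fraction * template.mean.max()
    return BrainMask(grid=template.grid, include=template.mean > threshold)
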