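"""Synthetic normal cohorts and atrophic patients.

The generator emulates the statistical structure of CAT12-style preprocessed
(spatially normalized, modulated, smoothed) gray-matter maps that normative
atrophy mapping assumes:

* a deterministic age/sex trend — linear gray-matter decline with age plus an
  additive sex offset,
* smooth between-subject variation — a stationary Gaussian random field
  obtained by convolving white noise with a Gaussian kernel of configurable
  FWHM and rescaling so the marginal (per-voxel) SD equals ``between_subject_sd``
  regardless of the kernel width,
* injectable focal atrophy — a multiplicative gray-matter reduction inside a
  mesiotemporal-like ellipsoidal region, optionally per hemisphere.

It makes no attempt at realistic anatomy; the point is that every downstream
stage (template construction, z-maps, subsample-consistency curves, knee
detection) can be exercised and validated without any cohort downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, NormMapError
from .grid import BrainMask, GMVolume, VoxelGrid, require_same_grid
from .io import FEMALE, MALE, SubjectRecord

_FWHM_TO_SIGMA = 1.0 / (8.0 * np.log(2.0)) ** 0.5


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic healthy cohort.

    ``baseline_mean`` is the expected gray-matter level (arbitrary units) of a
    female subject at the midpoint of ``age_range``; ``age_slope`` is the
    change per year (negative for decline); ``sex_offset`` is added for males.
    ``between_subject_sd`` is the marginal SD of the smooth subject-specific
    random field and ``noise_fwhm`` its spatial smoothness in mm.
    """

    grid: VoxelGrid
    n_subjects: int = 100
    age_range: tuple[int, int] = (50, 90)
    sex_ratio: float = 0.58  # fraction female
    baseline_mean: float = 10.0
    age_slope: float = -0.05  # a.u. per year
    sex_offset: float = -0.5  # additive for males
    between_subject_sd: float = 1.0
    noise_fwhm: float = 4.0  # mm
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise NormMapError("n_subjects must be >= 1")
        if self.between_subject_sd < 0:
            raise NormMapError("between_subject_sd must be >= 0")
        if self.baseline_mean <= 0:
            raise NormMapError("baseline_mean must be > 0")
        if self.age_range[0] > self.age_range[1]:
            raise NormMapError("age_range min must be <= max")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise NormMapError("sex_ratio must be in [0, 1]")

    @property
    def age_ref(self) -> float:
        """Reference age: midpoint of the range, so baseline_mean is the
        mid-cohort female mean."""
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass(frozen=True)
class AtrophySpec:
    """Focal atrophy: fractional GM reduction inside a region mask."""

    region_mask: BrainMask
    severity: float

    def __post_init__(self):
        if not (0.0 <= self.severity <= 1.0):
            raise NormMapError(f"severity must be in [0, 1], got {self.severity}")
        if not self.region_mask.include.any():
            raise EmptyMaskError("atrophy region mask is empty")


def _smooth_unit_field(shape, sigma_vox, rng) -> np.ndarray:
    """Stationary Gaussian field with unit marginal variance.

    White noise is convolved with a Gaussian kernel under periodic boundary
    conditions; the variance-reduction factor of the convolution (the sum of
    squared kernel weights) is computed exactly from an impulse response, so
    the rescaled field has marginal SD 1 independent of the kernel width.
    """
    white = rng.standard_normal(shape)
    if all(s == 0 for s in sigma_vox):
        return white
    smoothed = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
    norm = np.sqrt((kernel**2).sum())
    return smoothed / norm


def generate_subject(spec: SyntheticCohortSpec, age: int, sex: str,
                     rng: np.random.Generator, subject_id: str = "") -> GMVolume:
    """One synthetic gray-matter volume for a subject of given age and sex.

    The value at every voxel is ``baseline_mean + age_slope*(age - age_ref)
    + sex_offset*[sex == male] + noise`` clipped at zero, where the noise is
    the smooth random field described in the module docstring.
    """
    if not (spec.age_range[0] <= age <= spec.age_range[1]):
        raise NormMapError(
            f"age {age} outside cohort age_range {spec.age_range}"
        )
    if sex not in (FEMALE, MALE):
        raise NormMapError(f"sex must be '{FEMALE}' or '{MALE}', got {sex!r}")
    level = (
        spec.baseline_mean
        + spec.age_slope * (age - spec.age_ref)
        + (spec.sex_offset if sex == MALE else 0.0)
    )
    values = np.full(spec.grid.shape, level, dtype=np.float64)
    if spec.between_subject_sd > 0:
        sigma_vox = tuple(
            spec.noise_fwhm * _FWHM_TO_SIGMA / v for v in spec.grid.voxel_size
        )
        values = values + spec.between_subject_sd * _smooth_unit_field(
            spec.grid.shape, sigma_vox, rng
        )
    np.clip(values, 0.0, None, out=values)
    return GMVolume(grid=spec.grid, values=values, subject_id=subject_id)


def generate_cohort(spec: SyntheticCohortSpec):
    """Draw a full cohort: metadata records and volumes, aligned by index.

    Ages are uniform integers over ``age_range`` and sex is Bernoulli with
    probability ``sex_ratio`` of female; everything is reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    lo, hi = spec.age_range
    records, volumes = [], []
    for i in range(spec.n_subjects):
        age = int(rng.integers(lo, hi + 1))
        sex = FEMALE if rng.random() < spec.sex_ratio else MALE
        sid = f"syn{i:04d}"
        vol = generate_subject(spec, age, sex, rng, subject_id=sid)
        records.append(
            SubjectRecord(subject_id=sid, age=age, sex=sex, cohort="synthetic",
                          scanner="synthetic", volume_ref=f"{sid}.nii.gz")
        )
        volumes.append(vol)
    return records, volumes


def inject_atrophy(volume: GMVolume, atrophy: AtrophySpec) -> GMVolume:
    """Multiply voxels inside the region mask by ``1 - severity``."""
    require_same_grid(volume, atrophy.region_mask, "volume and atrophy mask")
    values = volume.values.copy()
    values[atrophy.region_mask.include] *= 1.0 - atrophy.severity
    return GMVolume(grid=volume.grid, values=values,
                    subject_id=volume.subject_id)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    acc = np.zeros(shape)
    for ax in range(3):
        acc += ((idx[ax] - center[ax]) / radii[ax]) ** 2
    return acc <= 1.0


def default_mesiotemporal_masks(grid: VoxelGrid):
    """Two disjoint ellipsoidal region masks, mirror-symmetric about the
    mid-sagittal (first-axis) plane — a stand-in for left/right mesiotemporal
    regions. Requires at least 8 voxels per axis."""
    nx, ny, nz = grid.shape
    if min(grid.shape) < 8:
        raise NormMapError(
            f"grid {grid.shape} too small for mesiotemporal masks (need >= 8 per axis)"
        )
    radii = (max(nx * 0.10, 1.0), max(ny * 0.12, 1.0), max(nz * 0.12, 1.0))
    # inferior-anterior placement, one blob per hemisphere
    cy, cz = ny * 0.40, nz * 0.35
    cx_left = (nx - 1) / 2.0 - nx * 0.22
    left = _ellipsoid(grid.shape, (cx_left, cy, cz), radii)
    # mirroring (not a second ellipsoid) guarantees equal voxel counts on
    # even-sized grids
    right = left[::-1, :, :].copy()
    if (left & right).any():
        raise NormMapError("hemispheric masks overlap; grid too small")
    return (
        BrainMask(grid=grid, include=left),
        BrainMask(grid=grid, include=right),
    )


def default_brain_mask(grid: VoxelGrid) -> BrainMask:
    """Everything except a one-voxel background rim (synthetic volumes have
    signal everywhere; the rim mimics the empty background of real maps)."""
    inc = np.zeros(grid.shape, dtype=bool)
    inc[1:-1, 1:-1, 1:-1] = True
    if not inc.any():
        inc[:] = True
    return BrainMask(grid=grid, include=inc)
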