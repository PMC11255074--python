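"""Template-subsampling consistency experiment.

For a patient and a matched pool of healthy subjects, and for each template
size n, repeat R times: draw n subjects at random, build a normal template,
compute the patient's z-map. The voxel-wise SD of z across the R repeats,
averaged over brain voxels valid in every repeat, is the consistency
statistic SD̄_spatial(n). Plotting it over n gives a decreasing curve whose
knee marks the template size beyond which adding healthy subjects stops
improving the stability of the atrophy estimate.

Randomness is counter-based: each (patient, n, repeat) triple owns an
independent, named RNG substream, so adding patients or reordering template
sizes never perturbs the draws of another cell, and the whole experiment is
bit-reproducible from a single seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyMaskError,
    GridMismatchError,
    NormMapError,
    PoolTooSmallError,
    TooFewSubjectsError,
)
from .grid import BrainMask, GMVolume, require_same_grid
from .io import SubjectRecord
from .templates import (
    DEFAULT_AGE_WINDOW,
    DEFAULT_EPSILON,
    DEFAULT_MASK_FRACTION,
    ZMap,
    brain_mask_from_template,
    build_template,
    compute_zmap,
    match_subjects,
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the subsampling experiment.

    Defaults mirror the reference protocol: templates grow from 3 to 100
    subjects, each size is re-drawn 100 times, matching uses the same sex and
    an inclusive ±2-year age window, and a patient is eligible only when at
    least ``min_pool`` matched healthy subjects exist.
    """

    n_min: int = 3
    n_max: int = 100
    repeats: int = 100
    age_window: int = DEFAULT_AGE_WINDOW
    min_pool: int = 100
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    #: brain-mask policy: fraction of the template-mean maximum, or an
    #: explicit BrainMask set at call time
    mask_fraction: float = DEFAULT_MASK_FRACTION

    def __post_init__(self):
        if not (2 <= self.n_min <= self.n_max):
            raise NormMapError(
                f"need 2 <= n_min <= n_max, got {self.n_min}..{self.n_max}"
            )
        if self.repeats < 2:
            raise NormMapError("repeats must be >= 2")
        if self.min_pool < self.n_max:
            raise NormMapError("min_pool must be >= n_max")


@dataclass
class ConsistencyCurve:
    """Per-patient series of (template size n, SD̄_spatial)."""

    patient_id: str
    points: list[tuple[int, float]]
    repeats: int

    def __post_init__(self):
        ns = [n for n, _ in self.points]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise NormMapError("curve n values must be strictly increasing")
        if any(v < 0 for _, v in self.points):
            raise NormMapError("SD̄_spatial values must be >= 0")

    @property
    def n_values(self) -> np.ndarray:
        return np.array([n for n, _ in self.points], dtype=int)

    @property
    def sd_values(self) -> np.ndarray:
        return np.array([v for _, v in self.points], dtype=float)


def substream(seed: int, patient_id: str, n: int, repeat: int) -> np.random.Generator:
    """Named RNG substream for one (patient, template size, repeat) cell."""
    key = (zlib.crc32(str(patient_id).encode("utf-8")), int(n), int(repeat))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def draw_template_subjects(
    pool: list, n: int, rng: np.random.Generator
) -> list:
    """n distinct pool entries, uniformly without replacement."""
    if n > len(pool):
        raise PoolTooSmallError(
            f"cannot draw {n} subjects from a pool of {len(pool)}",
            required=n,
            available=len(pool),
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def sd_across_repeats(zmaps: list[ZMap], ddof: int = 1):
    """Voxel-wise sample SD of z over repeats, on the intersection of the
    per-repeat validity masks.

    Returns ``(sd_field, combined_valid)``; the SD field is zero outside the
    combined validity mask.
    """
    if len(zmaps) < 2:
        raise TooFewSubjectsError("need >= 2 z-maps for an SD across repeats")
    first = zmaps[0]
    for m in zmaps[1:]:
        require_same_grid(first, m, "z-maps")
    # shifting every repeat by the first is an exact no-op for the SD but
    # removes cancellation error: identical repeats give exactly 0
    stack = np.stack([m.z - zmaps[0].z for m in zmaps])
    valid = np.logical_and.reduce([m.valid for m in zmaps])
    sd = np.zeros(first.grid.shape, dtype=np.float64)
    if valid.any():
        sd[valid] = stack[:, valid].std(axis=0, ddof=ddof)
    return sd, valid


def spatial_mean(field: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a field over mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("spatial mean over an empty mask")
    field = np.asarray(field, dtype=np.float64)
    if field.shape != mask.shape:
        raise GridMismatchError("field and mask shapes differ")
    return float(field[mask].mean())


def consistency_at_n(
    patient: GMVolume,
    pool_volumes: list[GMVolume],
    n: int,
    repeats: int,
    rng: np.random.Generator | None = None,
    epsilon: float = DEFAULT_EPSILON,
    brain_mask: BrainMask | None = None,
    mask_fraction: float = DEFAULT_MASK_FRACTION,
    rng_for_repeat=None,
) -> float:
    """SD̄_spatial for one template size.

    Composes draw → build_template → compute_zmap for each of ``repeats``
    repeats, then takes the voxel-wise SD across repeats and its spatial
    mean. ``rng_for_repeat(repeat_index)`` can supply the named per-repeat
    substreams; otherwise draws come sequentially from ``rng``.

    When the brain mask is not given explicitly it is derived from the
    *full-pool* template mean, so the support is identical across template
    sizes and repeats.
    """
    if rng_for_repeat is None:
        if rng is None:
            raise NormMapError("provide either rng or rng_for_repeat")
        rng_for_repeat = lambda r: rng  # noqa: E731 - sequential draws
    zmaps = []
    for r in range(repeats):
        drawn = draw_template_subjects(pool_volumes, n, rng_for_repeat(r))
        template = build_template(drawn)
        zmaps.append(compute_zmap(patient, template, epsilon=epsilon))
    sd_field, valid = sd_across_repeats(zmaps)
    if brain_mask is None:
        full = build_template(pool_volumes)
        brain_mask = brain_mask_from_template(full, fraction=mask_fraction)
    support = brain_mask.include & valid
    if not support.any():
        raise EmptyMaskError(
            "no voxel is both inside the brain mask and valid in all repeats"
        )
    return spatial_mean(sd_field, support)


def consistency_curve(
    patient: GMVolume,
    pool_volumes: list[GMVolume],
    config: ExperimentConfig,
    brain_mask: BrainMask | None = None,
    enforce_min_pool: bool = True,
) -> ConsistencyCurve:
    """SD̄_spatial over template sizes n_min..n_max for one patient."""
    pool_size = len(pool_volumes)
    if enforce_min_pool and pool_size < config.min_pool:
        raise PoolTooSmallError(
            f"patient {patient.subject_id!r}: matched pool has {pool_size} "
            f"subjects, {config.min_pool} required",
            required=config.min_pool,
            available=pool_size,
        )
    if pool_size < config.n_max:
        raise PoolTooSmallError(
            f"patient {patient.subject_id!r}: pool of {pool_size} cannot "
            f"support templates of {config.n_max}",
            required=config.n_max,
            available=pool_size,
        )
    if brain_mask is None:
        full = build_template(pool_volumes)
        brain_mask = brain_mask_from_template(full, fraction=config.mask_fraction)
    points = []
    for n in range(config.n_min, config.n_max + 1):
        value = consistency_at_n(
            patient,
            pool_volumes,
            n,
            config.repeats,
            epsilon=config.epsilon,
            brain_mask=brain_mask,
            rng_for_repeat=lambda r, n=n: substream(
                config.seed, patient.subject_id, n, r
            ),
        )
        points.append((n, value))
    return ConsistencyCurve(
        patient_id=patient.subject_id, points=points, repeats=config.repeats
    )


def summarize_knees(knee_ns: list[int]) -> dict:
    """Max / mean±SD / median / IQR of per-patient knee points."""
    arr = np.asarray(knee_ns, dtype=float)
    if arr.size == 0:
        raise NormMapError("no knee points to summarize")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "max": int(arr.max()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "n_patients": int(arr.size),
    }


def run_experiment(
    patients: list[tuple[SubjectRecord, GMVolume]],
    cohort: list[SubjectRecord],
    cohort_volumes: dict[str, GMVolume],
    config: ExperimentConfig,
    smoothing: float | None = None,
):
    """Full experiment: per-patient matched pool → curve → knee; summary.

    ``patients`` pairs each patient's metadata record with their volume;
    ``cohort_volumes`` maps healthy subject_id → volume. Patients whose
    matched pool is below ``config.min_pool`` are rejected up front, listed
    by id. Returns ``(results, summary)`` where results is a list of
    ``(record, ConsistencyCurve, KneePoint)`` and summary the knee-point
    statistics (max, mean±SD, median, IQR).
    """
    from .knee import find_knee  # deferred: knee module depends on curves

    ineligible = []
    pools = {}
    for record, _ in patients:
        matched = match_subjects(
            cohort, record.age, record.sex, age_window=config.age_window
        )
        if len(matched) < config.min_pool:
            ineligible.append((record.subject_id, len(matched)))
        pools[record.subject_id] = matched
    if ineligible:
        detail = ", ".join(f"{sid} ({have} matched)" for sid, have in ineligible)
        raise PoolTooSmallError(
            f"patients below the min_pool={config.min_pool} eligibility "
            f"threshold: {detail}",
            required=config.min_pool,
        )
    results = []
    knee_ns = []
    for record, volume in patients:
        pool_vols = [
            cohort_volumes[r.subject_id] for r in pools[record.subject_id]
        ]
        curve = consistency_curve(volume, pool_vols, config)
        knee = find_knee(curve, smoothing=smoothing)
        results.append((record, curve, knee))
        if knee.found:
            knee_ns.append(knee.n_at_knee)
    if not knee_ns:
        raise NormMapError("no knee point found for any patient")
    return results, summarize_knees(knee_ns)
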