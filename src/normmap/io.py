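"""Readers and writers: NIfTI-1 volumes, cohort CSV tables, curve CSVs, config.

Conventions
-----------
* Volumes are NIfTI-1 (``.nii`` / ``.nii.gz``); the data array round-trips
  bit-identically (written as float64) and the affine is preserved.
* Tables are comma-separated UTF-8 with a header row.
* Ages are integer years; fractional input ages are floored with a warning,
  matching how cohort demographics are reported in this field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import (
    DimensionalityError,
    DuplicateSubjectError,
    EmptyCurveError,
    InvalidFieldError,
    MissingColumnError,
    NonFiniteDataError,
    VolumeReadError,
)
from .grid import GMVolume, VoxelGrid

logger = logging.getLogger("normmap")

FEMALE = "female"
MALE = "male"

#: accepted spellings for each sex level (case-insensitive)
SEX_ALIASES = {
    FEMALE: {"female", "f", "w", "woman", "0"},
    MALE: {"male", "m", "man", "1"},
}

COHORT_COLUMNS = ["subject_id", "age", "sex", "cohort", "scanner", "volume_ref"]
CURVE_COLUMNS = ["n_subjects", "sd_spatial_mean", "patient_id", "repeats"]


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort metadata table."""

    subject_id: str
    age: int
    sex: str
    cohort: str = ""
    scanner: str = ""
    volume_ref: str = ""

    def __post_init__(self):
        if not (0 <= self.age <= 120):
            raise InvalidFieldError(
                f"subject {self.subject_id!r}: age {self.age} outside [0, 120]"
            )
        if self.sex not in (FEMALE, MALE):
            raise InvalidFieldError(
                f"subject {self.subject_id!r}: sex must be "
                f"'{FEMALE}' or '{MALE}', got {self.sex!r}"
            )


def normalize_sex(value) -> str:
    token = str(value).strip().lower()
    for level, aliases in SEX_ALIASES.items():
        if token in aliases:
            return level
    raise InvalidFieldError(f"unrecognized sex value {value!r}")


def _coerce_age(value, subject_id) -> int:
    try:
        age = float(value)
    except (TypeError, ValueError) as exc:
        raise InvalidFieldError(
            f"subject {subject_id!r}: unparseable age {value!r}"
        ) from exc
    if not math.isfinite(age):
        raise InvalidFieldError(f"subject {subject_id!r}: non-finite age")
    if age != int(age):
        logger.warning(
            "subject %r: fractional age %s floored to %d",
            subject_id, age, int(math.floor(age)),
        )
    return int(math.floor(age))


def read_volume(path) -> GMVolume:
    """Load a 3D NIfTI-1 gray-matter volume.

    Raises :class:`VolumeReadError` for unreadable files,
    :class:`DimensionalityError` for non-3D images and
    :class:`NonFiniteDataError` for NaN/Inf voxels.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeReadError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D volume, got {data.ndim}D shape {data.shape}"
        )
    if not np.isfinite(data).all():
        raise NonFiniteDataError(f"{path}: volume contains NaN or Inf voxels")
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(shape=data.shape, voxel_size=tuple(float(z) for z in zooms),
                     affine=img.affine)
    return GMVolume(grid=grid, values=data, subject_id=path.stem.removesuffix(".nii"))


def write_volume(volume: GMVolume, path) -> None:
    """Write a volume (or any 3D field via :func:`write_field`) to NIfTI-1."""
    write_field(volume.values, volume.grid, path)


def write_field(values: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write an arbitrary 3D scalar field on ``grid`` as float64 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), grid.affine_matrix)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def read_cohort_table(path) -> list[SubjectRecord]:
    """Read the subject metadata CSV into a list of :class:`SubjectRecord`.

    Sexes are normalized to {female, male} via an alias set; duplicate
    subject ids and unparseable ages raise distinct errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise DuplicateSubjectError(f"{path}: duplicate subject_id(s) {dupes}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=_coerce_age(row.age, row.subject_id),
                sex=normalize_sex(row.sex),
                cohort=str(row.cohort),
                scanner=str(row.scanner),
                volume_ref=str(row.volume_ref),
            )
        )
    return records


def write_cohort_table(records, path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "cohort": r.cohort,
                "scanner": r.scanner,
                "volume_ref": r.volume_ref,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    ).to_csv(path, index=False)


def write_curve(curve, path) -> None:
    """Serialize a consistency curve to CSV.

    Floats are written with 17 significant digits so the read-back equals
    the in-memory curve bit-for-bit.
    """
    if not curve.points:
        raise EmptyCurveError("refusing to write an empty consistency curve")
    df = pd.DataFrame(
        {
            "n_subjects": [n for n, _ in curve.points],
            "sd_spatial_mean": [v for _, v in curve.points],
            "patient_id": curve.patient_id,
            "repeats": curve.repeats,
        },
        columns=CURVE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_curve(path):
    from .consistency import ConsistencyCurve  # local import avoids a cycle

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise EmptyCurveError(f"{path}: curve file has no data rows")
    return ConsistencyCurve(
        patient_id=str(df["patient_id"].iloc[0]),
        points=[
            (int(n), float(v))
            for n, v in zip(df["n_subjects"], df["sd_spatial_mean"])
        ],
        repeats=int(df["repeats"].iloc[0]),
    )


def load_config(path) -> dict:
    """Load a nested key-value (YAML) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidFieldError(f"{path}: config root must be a mapping")
    return cfg


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; DEBUG when verbose."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
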