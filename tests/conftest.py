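import numpy as np
import pytest

from normmap import GMVolume, VoxelGrid, generate_cohort
from normmap.synthetic import SyntheticCohortSpec


@pytest.fixture(scope="session")
def grid16():
    return VoxelGrid(shape=(16, 16, 16))


@pytest.fixture(scope="session")
def small_cohort(grid16):
    """40 synthetic subjects on a 16^3 grid, narrow age band."""
    spec = SyntheticCohortSpec(
        grid=grid16, n_subjects=40, age_range=(60, 70), seed=3,
        between_subject_sd=1.0,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(values, subject_id="s", voxel_size=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    grid = VoxelGrid(shape=values.shape, voxel_size=voxel_size)
    return GMVolume(grid=grid, values=values, subject_id=subject_id)
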