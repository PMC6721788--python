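import numpy as np
import pytest

from threshcheck.image_io import BrainMask, ContrastImage, SubjectDataset, VolumeGrid
from threshcheck.synthetic_data import ClusterSpec, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_grid() -> VolumeGrid:
    return VolumeGrid((12, 12, 10), (2.0, 2.0, 2.0))


def make_dataset(values: np.ndarray, voxel_mm=(2.0, 2.0, 2.0)) -> SubjectDataset:
    """Dataset from an (n, x, y, z) array with a full mask."""
    grid = VolumeGrid(values.shape[1:], voxel_mm)
    images = [ContrastImage(grid, values[i]) for i in range(values.shape[0])]
    mask = BrainMask(grid, np.ones(grid.dims, dtype=bool))
    return SubjectDataset(images, mask)


@pytest.fixture(scope="session")
def null_dataset() -> SubjectDataset:
    """Pure-noise dataset (no signal), 12 subjects on a small smooth grid."""
    cfg = SimulationConfig(
        grid=VolumeGrid((16, 16, 12), (2.0, 2.0, 2.0)),
        n_subjects=12,
        clusters=(),
        subject_noise_sd=1.0,
        smooth_fwhm_mm=6.0,
        seed=97,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def signal_dataset() -> SubjectDataset:
    """Strong compact activation (core t ~ 8) amid smooth noise, 16 subjects."""
    grid = VolumeGrid((20, 20, 16), (2.0, 2.0, 2.0))
    cfg = SimulationConfig(
        grid=grid,
        n_subjects=16,
        clusters=(ClusterSpec((10, 10, 8), 10.0, 2.0),),
        subject_noise_sd=1.0,
        smooth_fwhm_mm=6.0,
        seed=11,
        smooth_template=False,
    )
    return simulate_dataset(cfg)
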