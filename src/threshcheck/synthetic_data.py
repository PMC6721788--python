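"""Synthetic multi-subject contrast datasets with known activation structure.

Each simulated subject image is ``template + smoothed noise``: the template
carries a handful of spherical activation clusters of varying extent, and
the between-subject noise is i.i.d. Gaussian white noise convolved with a
Gaussian kernel (FWHM in mm) and then rescaled so its voxelwise standard
deviation equals ``subject_noise_sd`` again.  With cluster amplitude ``a``,
noise sd ``s`` and ``n`` subjects, the expected one-sample t value in a
cluster core is approximately ``a / (s / sqrt(n))``; the presets use
``a/s = 1.5`` at n = 15-16, i.e. core t around 6, so that large clusters
survive every correction method while small ones sit near the margin.

Two presets emulate the statistical structure of typical group studies of
higher-order cognition: a 16-subject dataset on a 2 mm grid and a
15-subject dataset on a 3 mm grid, both smoothed at 8 mm FWHM, on
desk-scale reduced grids by default (full-size MNI-like grids behind a
flag).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import BrainMask, ContrastImage, SubjectDataset, VolumeGrid

__all__ = [
    "ClusterSpec",
    "SimulationConfig",
    "fwhm_to_sigma",
    "make_template",
    "ellipsoid_mask",
    "smooth_volume",
    "simulate_dataset",
    "preset_moral",
    "preset_wm",
]

#: sigma = FWHM / sqrt(8 ln 2)
_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a kernel of the given FWHM (mm)."""
    return float(fwhm_mm) * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class ClusterSpec:
    """A spherical activation: voxel-index center, radius (mm), amplitude."""

    center: tuple[int, int, int]
    radius_mm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    grid: VolumeGrid
    n_subjects: int
    clusters: tuple[ClusterSpec, ...]
    subject_noise_sd: float = 1.0
    smooth_fwhm_mm: float = 8.0
    seed: int = 0
    use_ellipsoid_mask: bool = False
    smooth_template: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.subject_noise_sd <= 0:
            raise ValueError("subject_noise_sd must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be non-negative")
        object.__setattr__(self, "clusters", tuple(self.clusters))


def make_template(grid: VolumeGrid, clusters: list[ClusterSpec] | tuple[ClusterSpec, ...]) -> ContrastImage:
    """Sum of spherical indicator clusters scaled by their amplitudes.

    A voxel belongs to a cluster when its mm distance from the cluster
    center (index difference scaled by voxel size) is at most ``radius_mm``;
    overlapping clusters add.
    """
    values = np.zeros(grid.dims, dtype=np.float64)
    coords = np.indices(grid.dims, dtype=np.float64)
    vm = np.asarray(grid.voxel_mm)
    for spec in clusters:
        c = spec.center
        if any(not (0 <= c[ax] < grid.dims[ax]) for ax in range(3)):
            raise ValueError(f"cluster center {c} outside grid {grid.dims}")
        d2 = sum(((coords[ax] - c[ax]) * vm[ax]) ** 2 for ax in range(3))
        values[d2 <= spec.radius_mm**2] += spec.amplitude
    return ContrastImage(grid, values)


def ellipsoid_mask(grid: VolumeGrid, fraction: float = 0.92) -> BrainMask:
    """Axis-aligned ellipsoidal 'brain' mask centered on the grid.

    Semi-axes are ``fraction`` times the half-extent of each axis.
    """
    coords = np.indices(grid.dims, dtype=np.float64)
    inside = np.zeros(grid.dims, dtype=np.float64)
    for ax in range(3):
        half = (grid.dims[ax] - 1) / 2.0
        semi = max(fraction * half, 0.5)
        inside += ((coords[ax] - half) / semi) ** 2
    return BrainMask(grid, inside <= 1.0)


def smooth_volume(values: np.ndarray, fwhm_mm: float, voxel_mm) -> np.ndarray:
    """Separable Gaussian smoothing, reflective boundaries, 4-sigma kernel."""
    if fwhm_mm == 0:
        return np.asarray(values, dtype=np.float64)
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in voxel_mm]
    return gaussian_filter(np.asarray(values, dtype=np.float64), sigma_vox,
                           mode="reflect", truncate=4.0)


def simulate_dataset(cfg: SimulationConfig) -> SubjectDataset:
    """Simulate ``template + smoothed, variance-renormalized noise`` per subject.

    Deterministic given ``cfg.seed``; each subject draws from an independent
    child stream.  By default the activation template is smoothed with the
    same kernel as the noise, mirroring how acquired images (signal and
    noise alike) pass through spatial smoothing — clusters then have
    realistic graded edges instead of hard spherical boundaries
    (``smooth_template=False`` restores the hard spheres).
    """
    template = make_template(cfg.grid, cfg.clusters).values
    if cfg.smooth_template and cfg.smooth_fwhm_mm > 0:
        template = smooth_volume(template, cfg.smooth_fwhm_mm, cfg.grid.voxel_mm)
    if cfg.use_ellipsoid_mask:
        mask = ellipsoid_mask(cfg.grid)
    else:
        mask = BrainMask(cfg.grid, np.ones(cfg.grid.dims, dtype=bool))
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    images = []
    for ss in children:
        rng = np.random.default_rng(ss)
        noise = rng.standard_normal(cfg.grid.dims)
        if cfg.smooth_fwhm_mm > 0:
            noise = smooth_volume(noise, cfg.smooth_fwhm_mm, cfg.grid.voxel_mm)
            # smoothing deflates variance; renormalize so the realized field
            # keeps sd == subject_noise_sd
            noise /= noise.std()
            noise *= cfg.subject_noise_sd
        else:
            noise *= cfg.subject_noise_sd
        images.append(ContrastImage(cfg.grid, template + noise))
    return SubjectDataset(images, mask)


# Preset cluster layouts: fractional grid positions so the same layout scales
# to the full-size grids; radii are physical (mm) and amplitudes are in units
# of the subject noise sd.  Each preset combines (i) a tiny focal cluster,
# (ii) two mid-size foci whose smoothed cores reach t around 4.8 and whose
# suprathreshold extents hover near typical cluster-size thresholds, and
# (iii) one broad moderate activation field whose per-voxel t sits right at
# the p < 0.001 forming threshold.  Group contrast maps of higher-order
# cognition look like this — extended moderate effects with embedded foci
# and no towering peaks — and this structure is what separates voxel-wise,
# cluster-extent and threshold-free inference: voxel-wise FWE catches only
# the noise-located peaks of the broad field, extent thresholding catches
# its percolating suprathreshold patches, and TFCE accumulates spatial
# support across the whole field.
_MORAL_CLUSTERS = (
    ((0.30, 0.29, 0.47), 3.0, 1.5),
    ((0.16, 0.30, 0.50), 8.0, 1.4),
    ((0.80, 0.28, 0.44), 8.0, 1.4),
    ((0.50, 0.50, 0.50), 24.0, 1.0),
)
_WM_CLUSTERS = (
    ((0.30, 0.31, 0.46), 4.5, 1.5),
    ((0.14, 0.28, 0.50), 9.5, 1.4),
    ((0.86, 0.30, 0.46), 9.5, 1.4),
    ((0.50, 0.50, 0.50), 24.0, 1.0),
)


def _build_preset(
    seed: int,
    grid_small: tuple[int, int, int],
    grid_full: tuple[int, int, int],
    voxel_mm: float,
    n_subjects: int,
    layout,
    full_size: bool,
) -> SimulationConfig:
    dims = grid_full if full_size else grid_small
    grid = VolumeGrid(dims, (voxel_mm,) * 3)
    clusters = tuple(
        ClusterSpec(
            tuple(int(round(f * (d - 1))) for f, d in zip(frac, dims)),
            radius_mm,
            amplitude,
        )
        for frac, radius_mm, amplitude in layout
    )
    return SimulationConfig(
        grid=grid,
        n_subjects=n_subjects,
        clusters=clusters,
        subject_noise_sd=1.0,
        smooth_fwhm_mm=8.0,
        seed=seed,
        use_ellipsoid_mask=True,
    )


def preset_moral(seed: int, full_size: bool = False) -> SimulationConfig:
    """16-subject moral-dilemma-like dataset: 2 mm grid, 8 mm smoothing.

    Reduced 40x48x34 grid by default; 79x95x68 with ``full_size``.
    """
    return _build_preset(seed, (40, 48, 34), (79, 95, 68), 2.0, 16,
                         _MORAL_CLUSTERS, full_size)


def preset_wm(seed: int, full_size: bool = False) -> SimulationConfig:
    """15-subject working-memory-like dataset: 3 mm grid, 8 mm smoothing.

    Reduced 30x32x26 grid by default; 53x63x46 with ``full_size``.
    """
    return _build_preset(seed, (30, 32, 26), (53, 63, 46), 3.0, 15,
                         _WM_CLUSTERS, full_size)
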