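"""Second-level one-sample inference: t maps, pseudo-t maps, ResMS, p<->t.

The group model is the one-sample design on per-subject contrast images:
t = mean / (sd / sqrt(n)) with the (n-1)-denominator sd, df = n - 1.  The
pseudo-t variant divides by a spatially smoothed variance map instead —
variance smoothing stabilizes the denominator at low df and is the
statistic used by nonparametric permutation mapping; at 0 mm smoothing it
reduces exactly to the ordinary t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter

from .image_io import SubjectDataset, VolumeGrid
from .synthetic_data import fwhm_to_sigma

__all__ = [
    "StatMap",
    "ResMSMap",
    "one_sample_t",
    "pseudo_t",
    "t_from_p",
    "uncorrected_familywise_rate",
    "SD_ZERO_SENTINEL",
]

#: t value assigned where sd == 0 but mean != 0 (degenerate voxel)
SD_ZERO_SENTINEL = 1e6


@dataclass
class StatMap:
    grid: VolumeGrid
    values: np.ndarray
    df: int
    kind: str = "t"  # "t" or "pseudo_t"

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.grid.dims:
            raise ValueError("stat map shape does not match grid")
        if self.df < 1:
            raise ValueError("df must be positive")
        if self.kind not in ("t", "pseudo_t"):
            raise ValueError(f"unknown stat kind {self.kind!r}")


@dataclass
class ResMSMap:
    """Residual mean square (voxelwise variance across subjects)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.grid.dims:
            raise ValueError("ResMS map shape does not match grid")


def _mean_var(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = data.mean(axis=0)
    var = data.var(axis=0, ddof=1)
    return mean, var


def _t_from_mean_var(mean: np.ndarray, var: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    zero_sd = var == 0
    t[zero_sd & (mean == 0)] = 0.0
    deg = zero_sd & (mean != 0)
    t[deg] = np.sign(mean[deg]) * SD_ZERO_SENTINEL
    return t


def one_sample_t(dataset: SubjectDataset) -> tuple[StatMap, ResMSMap]:
    """Voxelwise one-sample t map and residual mean-square map.

    Out-of-mask voxels are set to 0 in both maps.  Degenerate voxels
    (sd == 0, mean != 0) get the signed sentinel ``SD_ZERO_SENTINEL``.
    """
    n = dataset.n_subjects
    data = dataset.data()
    mask = dataset.mask.inside
    mean, var = _mean_var(np.where(mask, data, 0.0))
    t = _t_from_mean_var(mean, var, n)
    t[~mask] = 0.0
    var[~mask] = 0.0
    return (
        StatMap(dataset.grid, t, df=n - 1, kind="t"),
        ResMSMap(dataset.grid, var),
    )


def smooth_in_mask(
    field: np.ndarray, mask: np.ndarray, fwhm_mm: float, voxel_mm
) -> np.ndarray:
    """Mask-normalized Gaussian smoothing (out-of-mask voxels carry no weight).

    Brain-edge voxels are not diluted by out-of-mask zeros: the smoothed
    field is the ratio of the smoothed masked field to the smoothed mask.
    """
    if fwhm_mm == 0:
        return np.asarray(field, dtype=np.float64)
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in voxel_mm]
    maskf = mask.astype(np.float64)
    num = gaussian_filter(np.where(mask, field, 0.0), sigma_vox, mode="reflect",
                          truncate=4.0)
    den = gaussian_filter(maskf, sigma_vox, mode="reflect", truncate=4.0)
    out = np.zeros_like(num)
    inside = den > 0
    out[inside] = num[inside] / den[inside]
    out[~mask] = 0.0
    return out


def pseudo_t(dataset: SubjectDataset, var_smooth_fwhm_mm: float = 8.0) -> StatMap:
    """Pseudo-t map: mean over sqrt(smoothed variance / n).

    Only the variance (denominator) is smoothed, by mask-normalized Gaussian
    convolution at ``var_smooth_fwhm_mm``; 0 mm reduces exactly to
    :func:`one_sample_t`.
    """
    n = dataset.n_subjects
    data = dataset.data()
    mask = dataset.mask.inside
    mean, var = _mean_var(np.where(mask, data, 0.0))
    svar = smooth_in_mask(var, mask, var_smooth_fwhm_mm, dataset.grid.voxel_mm)
    t = _t_from_mean_var(mean, svar, n)
    t[~mask] = 0.0
    kind = "pseudo_t" if var_smooth_fwhm_mm > 0 else "t"
    return StatMap(dataset.grid, t, df=n - 1, kind=kind)


def t_from_p(p: float, df: int) -> float:
    """One-sided upper-tail Student-t quantile: P(T_df >= t) = p."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if df < 1:
        raise ValueError("df must be positive")
    return float(stats.t.isf(p, df))


def uncorrected_familywise_rate(alpha: float, n_tests: int) -> float:
    """P(at least one false positive) for n independent tests at level alpha.

    1 - (1 - alpha)^n, computed in log space; at whole-brain voxel counts
    this saturates to 1.0 in double precision.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.expm1(n_tests * np.log1p(-alpha)))
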