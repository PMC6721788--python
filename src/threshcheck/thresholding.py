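"""The five multiple-comparison correction conditions, implemented in-repo.

Conditions compared (one-sided, positive tail throughout — the contrasts of
interest are directional group activations):

* ``snpm_voxel``   — permutation (sign-flip) voxel-wise FWE on the pseudo-t map.
* ``snpm_cluster`` — permutation cluster-extent FWE on the pseudo-t map at a
  p < 0.001 cluster-forming threshold.
* ``clustsim``     — Monte-Carlo cluster-size threshold assuming pure Gaussian
  smoothness (estimated from the data residuals with the ACF model
  constrained to its Gaussian component).
* ``clustsim_acf`` — the same Monte-Carlo procedure with noise generated from
  the fitted mixed Gaussian+exponential ACF.
* ``tfce``         — threshold-free cluster enhancement of the t map with
  permutation FWE on the maximum TFCE score.

Permutation inference uses the sign-flipping null of the one-sample design:
the identity flip is always included, all 2^n flips are enumerated exactly
when feasible, and the critical value is the ceil((1-alpha)*P)-th smallest
null maximum, which keeps the corrected p of anything strictly above it at
or below alpha under the permutation distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .acf_noise import (
    ACFParams,
    _generate_noise_batch,
    dataset_residual_acf,
    smoothness_fwhm_from_b,
)
from .glm import StatMap, _t_from_mean_var, one_sample_t, smooth_in_mask, t_from_p
from .image_io import BrainMask, SubjectDataset, VolumeGrid
from .synthetic_data import fwhm_to_sigma

__all__ = [
    "METHOD_NAMES",
    "ThresholdConfig",
    "ThresholdResult",
    "ClusterLabeling",
    "label_clusters",
    "sign_flip_matrix",
    "sign_flip_null",
    "snpm_voxelwise",
    "snpm_clusterwise",
    "mc_cluster_threshold",
    "clustsim_threshold",
    "tfce_transform",
    "tfce_fwe",
    "run_all_methods",
]

#: The five correction conditions, in canonical order.
METHOD_NAMES = ("snpm_voxel", "snpm_cluster", "clustsim", "clustsim_acf", "tfce")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ThresholdConfig:
    """Shared settings for all five correction conditions.

    Defaults follow common end-user guidance: cluster-forming p < 0.001,
    corrected alpha 0.05, 5000 permutations.  ``connectivity`` (18 = faces +
    edges) is shared across cluster methods and TFCE so the conditions stay
    comparable.  ``var_smooth_fwhm_mm`` is the pseudo-t variance-smoothing
    width applied by the two permutation (SnPM-style) conditions; the
    default 0 mm matches the tool's own default (no variance smoothing,
    pseudo-t = t), and 8 mm is the conventional choice when smoothing is
    wanted at low df.
    """

    cluster_forming_p: float = 0.001
    corrected_alpha: float = 0.05
    n_permutations: int = 5000
    n_mc_iterations: int = 10000
    connectivity: int = 18
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_n_steps: int = 100
    seed: int = 0
    var_smooth_fwhm_mm: float = 0.0
    acf_r_max_mm: float = 12.0
    acf_cube_dims: tuple[int, int, int] = (12, 12, 12)

    def __post_init__(self) -> None:
        if not 0 < self.cluster_forming_p < 1:
            raise ValueError("cluster_forming_p must be in (0, 1)")
        if not 0 < self.corrected_alpha <= 1:
            raise ValueError("corrected_alpha must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")


@dataclass
class ThresholdResult:
    """Binary survivor map plus the numeric cutoffs actually applied."""

    method: str
    survivors: np.ndarray
    n_survivors: int
    thresholds: dict
    corrected_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ClusterLabeling:
    labels: np.ndarray
    sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def label_clusters(binary: np.ndarray, connectivity: int = 18) -> ClusterLabeling:
    """3D connected components: 6 = faces, 18 = +edges, 26 = +corners."""
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(binary, structure=_structure(connectivity))
    if n == 0:
        return ClusterLabeling(labels, [])
    sizes = np.bincount(labels.ravel())[1:]
    return ClusterLabeling(labels, [int(s) for s in sizes])


# ---------------------------------------------------------------------------
# Sign-flipping permutation machinery
# ---------------------------------------------------------------------------


def sign_flip_matrix(n: int, n_permutations: int, seed: int) -> np.ndarray:
    """(P, n) matrix of subject sign flips; row 0 is always the identity.

    When 2^n <= n_permutations, all 2^n flips are enumerated exactly
    (P = 2^n); otherwise P = n_permutations rows: identity plus
    independently drawn random flips.
    """
    if n < 2:
        raise ValueError("need at least two subjects to flip")
    if n <= 30 and 2**n <= n_permutations:
        return np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = rng.choice([-1.0, 1.0], size=(n_permutations - 1, n))
    return np.vstack([np.ones((1, n)), rows])


def _perm_stat_maps(
    dataset: SubjectDataset, flips: np.ndarray, var_smooth_fwhm_mm: float
) -> Iterator[np.ndarray]:
    """Yield the t (or pseudo-t) map under each sign flip, identity first.

    Sign flips leave each subject's sum of squares unchanged, so per-flip
    variance follows from the per-flip mean alone; only the variance
    smoothing (when requested) needs a pass over the volume per flip.
    """
    n = dataset.n_subjects
    mask = dataset.mask.inside
    vm = dataset.grid.voxel_mm
    data = np.where(mask, dataset.data(), 0.0)
    dims = data.shape[1:]
    sumsq = (data**2).sum(axis=0)
    flat = data.reshape(n, -1)
    chunk = 64
    for start in range(0, flips.shape[0], chunk):
        means = (flips[start : start + chunk] @ flat) / n
        for row in means:
            mean = row.reshape(dims)
            var = np.maximum((sumsq - n * mean**2) / (n - 1), 0.0)
            if var_smooth_fwhm_mm > 0:
                var = smooth_in_mask(var, mask, var_smooth_fwhm_mm, vm)
            t = _t_from_mean_var(mean, var, n)
            t[~mask] = 0.0
            yield t


def sign_flip_null(
    dataset: SubjectDataset,
    n_permutations: int,
    seed: int,
    statistic: Callable[[SubjectDataset], object],
) -> list[float]:
    """Per-permutation maximum of an arbitrary statistic under sign flips.

    ``statistic`` maps a dataset to a :class:`~threshcheck.glm.StatMap`, a
    plain array (maximum taken over in-mask voxels) or a scalar (used as
    is, e.g. a maximum cluster extent).  Row 0 of the returned list is the
    observed (identity-flip) value.
    """
    flips = sign_flip_matrix(dataset.n_subjects, n_permutations, seed)
    data = dataset.data()
    mask = dataset.mask.inside
    out: list[float] = []
    for s in flips:
        flipped = dataset.with_images(data * s[:, None, None, None])
        m = statistic(flipped)
        if isinstance(m, StatMap):
            m = m.values
        arr = np.asarray(m, dtype=np.float64)
        out.append(float(arr) if arr.ndim == 0 else float(arr[mask].max()))
    return out


def _critical_value(null: np.ndarray, alpha: float) -> float:
    """ceil((1 - alpha) * P)-th smallest null value (order-statistic rule)."""
    null = np.sort(np.asarray(null, dtype=np.float64))
    P = len(null)
    m = int(np.ceil((1.0 - alpha) * P))
    m = min(max(m, 1), P)
    return float(null[m - 1])


def _corrected_p(null_sorted: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """P(null >= observed) under the permutation distribution (identity included)."""
    P = len(null_sorted)
    counts = P - np.searchsorted(null_sorted, observed, side="left")
    return counts / P


def _smallest_extent(null_extents: np.ndarray, alpha: float) -> int:
    """Smallest k with P(max null extent >= k) <= alpha."""
    null_sorted = np.sort(np.asarray(null_extents))
    P = len(null_sorted)
    k = 1
    kmax = int(null_sorted[-1]) + 1
    candidates = np.arange(1, kmax + 1)
    frac_ge = (P - np.searchsorted(null_sorted, candidates, side="left")) / P
    hits = np.nonzero(frac_ge <= alpha)[0]
    return int(candidates[hits[0]]) if len(hits) else kmax


# ---------------------------------------------------------------------------
# SnPM-style permutation FWE
# ---------------------------------------------------------------------------


def snpm_voxelwise(dataset: SubjectDataset, cfg: ThresholdConfig) -> ThresholdResult:
    """Permutation voxel-wise FWE on the variance-smoothed pseudo-t map."""
    mask = dataset.mask.inside
    flips = sign_flip_matrix(dataset.n_subjects, cfg.n_permutations, cfg.seed)
    observed = None
    maxima = []
    for i, tmap in enumerate(
        _perm_stat_maps(dataset, flips, cfg.var_smooth_fwhm_mm)
    ):
        if i == 0:
            observed = tmap
        maxima.append(tmap[mask].max())
    null = np.sort(np.array(maxima))
    crit = _critical_value(null, cfg.corrected_alpha)
    p_map = np.ones(observed.shape)
    p_map[mask] = _corrected_p(null, observed[mask])
    # survival means corrected p <= alpha; with ties in the null (identity
    # always included) this is strictly stronger than observed >= critical
    survivors = (p_map <= cfg.corrected_alpha) & mask
    return ThresholdResult(
        method="snpm_voxel",
        survivors=survivors,
        n_survivors=int(survivors.sum()),
        thresholds={"critical_pseudo_t": crit, "n_permutations": len(null)},
        corrected_p=p_map,
    )


def snpm_clusterwise(dataset: SubjectDataset, cfg: ThresholdConfig) -> ThresholdResult:
    """Permutation cluster-extent FWE on the pseudo-t map.

    The forming threshold is the Student-t upper quantile at
    ``cluster_forming_p``; the null statistic is the maximum cluster extent
    under each sign flip at the same forming threshold.
    """
    mask = dataset.mask.inside
    df = dataset.n_subjects - 1
    t_thr = t_from_p(cfg.cluster_forming_p, df)
    structure = _structure(cfg.connectivity)
    flips = sign_flip_matrix(dataset.n_subjects, cfg.n_permutations, cfg.seed)
    observed = None
    null_ext = []
    for i, tmap in enumerate(
        _perm_stat_maps(dataset, flips, cfg.var_smooth_fwhm_mm)
    ):
        if i == 0:
            observed = tmap
        binary = (tmap >= t_thr) & mask
        labels, n = ndimage.label(binary, structure=structure)
        null_ext.append(int(np.bincount(labels.ravel())[1:].max()) if n else 0)
    null_ext = np.array(null_ext)
    k_star = _smallest_extent(null_ext, cfg.corrected_alpha)
    obs_binary = (observed >= t_thr) & mask
    labeling = label_clusters(obs_binary, cfg.connectivity)
    survivors = np.zeros_like(mask)
    for idx, size in enumerate(labeling.sizes, start=1):
        if size >= k_star:
            survivors |= labeling.labels == idx
    return ThresholdResult(
        method="snpm_cluster",
        survivors=survivors,
        n_survivors=int(survivors.sum()),
        thresholds={
            "t_threshold": t_thr,
            "critical_extent": k_star,
            "n_permutations": len(null_ext),
        },
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-size thresholding (3DClustSim-style)
# ---------------------------------------------------------------------------


def mc_cluster_threshold(
    mask: BrainMask,
    noise_model: ACFParams | dict,
    cfg: ThresholdConfig,
) -> int:
    """Cluster-extent threshold k* from Monte-Carlo simulation of null fields.

    Each iteration draws a unit-variance field on the mask's bounding-box
    grid — white noise smoothed to ``fwhm_mm`` (Gaussian model, periodic
    boundaries so the field is stationary and the variance normalization is
    spatially uniform) or cube-wise correlated noise from the fitted ACF —
    thresholds it at the standard-normal quantile of ``cluster_forming_p``,
    masks it, and records the maximum cluster extent.  k* is the smallest
    extent whose exceedance fraction is at most ``corrected_alpha``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    grid = mask.grid
    z_thr = float(stats.norm.isf(cfg.cluster_forming_p))
    structure = _structure(cfg.connectivity)
    inside = mask.inside
    use_acf = isinstance(noise_model, ACFParams)
    if not use_acf:
        fwhm = float(noise_model["fwhm_mm"])
        sigma_vox = [fwhm_to_sigma(fwhm) / v for v in grid.voxel_mm]
    maxima = np.empty(cfg.n_mc_iterations, dtype=np.int64)
    chunk = max(1, min(256, int(2**27 // max(grid.n_voxels, 1))))
    it = 0
    while it < cfg.n_mc_iterations:
        m = min(chunk, cfg.n_mc_iterations - it)
        if use_acf:
            fields = _generate_noise_batch(noise_model, grid, cfg.acf_cube_dims,
                                           rng, m)
        else:
            fields = rng.standard_normal((m, *grid.dims))
            if fwhm > 0:
                for j in range(m):
                    f = ndimage.gaussian_filter(fields[j], sigma_vox, mode="wrap",
                                                truncate=4.0)
                    fields[j] = f / f.std()
        for j in range(m):
            binary = (fields[j] >= z_thr) & inside
            labels, n = ndimage.label(binary, structure=structure)
            maxima[it + j] = int(np.bincount(labels.ravel())[1:].max()) if n else 0
        it += m
    return _smallest_extent(maxima, cfg.corrected_alpha)


def clustsim_threshold(
    dataset: SubjectDataset,
    cfg: ThresholdConfig,
    use_acf: bool,
    noise_model: ACFParams | dict | None = None,
    k_star: int | None = None,
) -> ThresholdResult:
    """Monte-Carlo cluster-size thresholding of the one-sample t map.

    The noise model is estimated from the dataset's own residuals: the full
    mixed ACF when ``use_acf`` is set, otherwise a pure-Gaussian smoothness
    (ACF fit constrained to a = 1, converted to the equivalent
    smoothing-kernel FWHM).  ``noise_model`` / ``k_star`` may be supplied to
    reuse a previous calibration on the same mask.
    """
    tmap, _ = one_sample_t(dataset)
    mask = dataset.mask
    t_thr = t_from_p(cfg.cluster_forming_p, tmap.df)
    if k_star is None:
        if noise_model is None:
            if use_acf:
                noise_model = dataset_residual_acf(dataset, cfg.acf_r_max_mm)
            else:
                g = dataset_residual_acf(dataset, cfg.acf_r_max_mm, fix_a=1.0)
                noise_model = {"fwhm_mm": smoothness_fwhm_from_b(g.b)}
        k_star = mc_cluster_threshold(mask, noise_model, cfg)
    binary = (tmap.values >= t_thr) & mask.inside
    labeling = label_clusters(binary, cfg.connectivity)
    survivors = np.zeros_like(mask.inside)
    for idx, size in enumerate(labeling.sizes, start=1):
        if size >= k_star:
            survivors |= labeling.labels == idx
    thresholds = {"t_threshold": t_thr, "k_star": int(k_star)}
    if isinstance(noise_model, ACFParams):
        thresholds["acf"] = (noise_model.a, noise_model.b, noise_model.c)
    elif isinstance(noise_model, dict):
        thresholds["fwhm_mm"] = noise_model["fwhm_mm"]
    return ThresholdResult(
        method="clustsim_acf" if use_acf else "clustsim",
        survivors=survivors,
        n_survivors=int(survivors.sum()),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Threshold-free cluster enhancement
# ---------------------------------------------------------------------------


def _tfce_values(
    values: np.ndarray, E: float, H: float, n_steps: int, structure: np.ndarray
) -> np.ndarray:
    """Discrete TFCE integral over n_steps equal height slabs."""
    out = np.zeros_like(values, dtype=np.float64)
    pos = values > 0
    if not pos.any():
        return out
    # crop to the positive bounding box; everything outside contributes 0
    idx = np.nonzero(pos)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    vals = values[sl]
    out_c = out[sl]
    h_max = float(vals.max())
    dh = h_max / n_steps
    for step in range(1, n_steps + 1):
        h = h_max * step / n_steps
        binary = vals >= h
        labels, n = ndimage.label(binary, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel()).astype(np.float64)
        support = np.power(sizes, E)
        lab_b = labels[binary]
        out_c[binary] += support[lab_b] * (h**H) * dh
    return out


def tfce_transform(stat: StatMap, cfg: ThresholdConfig) -> np.ndarray:
    """TFCE map: sum over height slabs of extent^E * height^H * dh.

    At each of ``tfce_n_steps`` equal height thresholds up to the map
    maximum, every suprathreshold voxel accrues the size of its connected
    component raised to E times the height raised to H.  Nonpositive
    statistics map to 0; an all-nonpositive map yields all zeros.
    """
    return _tfce_values(
        np.asarray(stat.values, dtype=np.float64),
        cfg.tfce_E,
        cfg.tfce_H,
        cfg.tfce_n_steps,
        _structure(cfg.connectivity),
    )


def tfce_fwe(dataset: SubjectDataset, cfg: ThresholdConfig) -> ThresholdResult:
    """Permutation FWE on the maximum TFCE score of the t map."""
    mask = dataset.mask.inside
    structure = _structure(cfg.connectivity)
    flips = sign_flip_matrix(dataset.n_subjects, cfg.n_permutations, cfg.seed)
    observed = None
    maxima = []
    for i, tmap in enumerate(_perm_stat_maps(dataset, flips, 0.0)):
        tf = _tfce_values(tmap, cfg.tfce_E, cfg.tfce_H, cfg.tfce_n_steps, structure)
        if i == 0:
            observed = tf
        maxima.append(tf[mask].max())
    null = np.sort(np.array(maxima))
    crit = _critical_value(null, cfg.corrected_alpha)
    p_map = np.ones(observed.shape)
    p_map[mask] = _corrected_p(null, observed[mask])
    survivors = (p_map <= cfg.corrected_alpha) & (observed > 0) & mask
    return ThresholdResult(
        method="tfce",
        survivors=survivors,
        n_survivors=int(survivors.sum()),
        thresholds={"critical_tfce": crit, "n_permutations": len(null)},
        corrected_p=p_map,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def derive_seed(base: int, *keys: int) -> int:
    """Deterministic child seed (< 2^31) from a base seed and integer keys."""
    ss = np.random.SeedSequence([int(base), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % 2**31)


def run_all_methods(
    dataset: SubjectDataset, cfg: ThresholdConfig
) -> tuple[list[ThresholdResult], pd.DataFrame]:
    """Run the five conditions with distinct seed streams off ``cfg.seed``.

    Returns the five :class:`ThresholdResult` objects (canonical order) and
    a survivor-count table.
    """
    results = []
    for idx, name in enumerate(METHOD_NAMES):
        method_cfg = replace(cfg, seed=derive_seed(cfg.seed, idx))
        if name == "snpm_voxel":
            results.append(snpm_voxelwise(dataset, method_cfg))
        elif name == "snpm_cluster":
            results.append(snpm_clusterwise(dataset, method_cfg))
        elif name == "clustsim":
            results.append(clustsim_threshold(dataset, method_cfg, use_acf=False))
        elif name == "clustsim_acf":
            results.append(clustsim_threshold(dataset, method_cfg, use_acf=True))
        elif name == "tfce":
            results.append(tfce_fwe(dataset, method_cfg))
    table = pd.DataFrame(
        {
            "method": [r.method for r in results],
            "n_survivors": [r.n_survivors for r in results],
        }
    )
    return results, table
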