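"""Mixed Gaussian+exponential spatial autocorrelation: model, fit, noise.

The spatial autocorrelation of smoothed fMRI noise is modelled as

    rho(r) = a * exp(-r^2 / (2 b^2)) + (1 - a) * exp(-r / c)

with ``r`` the mm distance between two voxels, ``a`` in [0, 1] the Gaussian
mixing fraction, ``b`` (mm) the Gaussian width and ``c`` (mm) the
exponential decay length.  Pure Gaussian smoothness is the ``a = 1`` special
case; the heavy exponential tail (``a < 1``) is what the classic
Gaussian-random-field assumption misses in real data.

Spatially-autocorrelated noise is generated cube-wise: the grid's bounding
box is tiled with non-overlapping cubes, each cube's correlation matrix is
built from the model and Cholesky-factorized, and ``L @ z`` with standard
normal ``z`` gives a unit-variance correlated field.  Cubes are mutually
independent (correlation across a cube boundary is zero by construction);
this tiling artifact is intentional — it mirrors the memory-bounded way the
noise is produced in practice — and the default cube of 12^3 voxels keeps
the covariance factorization desk-sized (a 30^3 cube needs tens of GB).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .image_io import BrainMask, ContrastImage, SubjectDataset, VolumeGrid

__all__ = [
    "ACFParams",
    "NoiseField",
    "NoiseInjectionConfig",
    "acf",
    "empirical_acf",
    "fit_acf",
    "fit_acf_curve",
    "dataset_residual_acf",
    "smoothness_fwhm_from_b",
    "build_covariance",
    "generate_noise",
    "inject_noise",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ACFParams:
    """Parameters (a, b, c) of the mixed Gaussian+exponential ACF."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError(f"a must be in [0, 1], got {self.a}")
        if self.b <= 0 or self.c <= 0:
            raise ValueError(f"b and c must be positive, got b={self.b}, c={self.c}")


@dataclass
class NoiseField:
    grid: VolumeGrid
    values: np.ndarray
    params: ACFParams
    seed: int

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.grid.dims:
            raise ValueError("noise field shape does not match grid")


@dataclass(frozen=True)
class NoiseInjectionConfig:
    """Cube size (voxels), noise magnitude as a fraction of contrast strength, seed."""

    cube_dims: tuple[int, int, int] = (12, 12, 12)
    magnitude_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 2 for d in self.cube_dims):
            raise ValueError("each cube dimension must be >= 2")
        if self.magnitude_fraction < 0:
            raise ValueError("magnitude_fraction must be non-negative")


def acf(params: ACFParams, r) -> np.ndarray | float:
    """Model correlation at mm distance(s) ``r`` (scalar or array, r >= 0)."""
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(r_arr < 0):
        raise ValueError("distances must be non-negative")
    val = params.a * np.exp(-(r_arr**2) / (2.0 * params.b**2)) + (
        1.0 - params.a
    ) * np.exp(-r_arr / params.c)
    return float(val) if np.isscalar(r) else val


def smoothness_fwhm_from_b(b: float) -> float:
    """Smoothing-kernel FWHM (mm) whose white-noise ACF has Gaussian width b.

    Convolving white noise with a Gaussian kernel of sigma_k produces an
    autocorrelation that is Gaussian with sigma = sqrt(2) * sigma_k, i.e.
    rho(r) = exp(-r^2 / (2 b^2)) with b = sqrt(2) sigma_k.  Hence
    FWHM_kernel = b * sqrt(4 ln 2).
    """
    return float(b) * float(np.sqrt(4.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Empirical ACF estimation and model fitting
# ---------------------------------------------------------------------------


def _half_space_offsets(voxel_mm, r_max_mm: float):
    """Integer-lag offsets with 0 < ||offset * voxel_mm|| <= r_max_mm.

    Only one representative of each {d, -d} pair is returned (correlation is
    symmetric in the lag).
    """
    max_lag = [int(np.floor(r_max_mm / v)) for v in voxel_mm]
    offsets = []
    for di in range(0, max_lag[0] + 1):
        for dj in range(-max_lag[1], max_lag[1] + 1):
            for dk in range(-max_lag[2], max_lag[2] + 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                # half space: first nonzero component positive
                if di == 0 and (dj < 0 or (dj == 0 and dk < 0)):
                    continue
                r = np.sqrt(
                    (di * voxel_mm[0]) ** 2
                    + (dj * voxel_mm[1]) ** 2
                    + (dk * voxel_mm[2]) ** 2
                )
                if r <= r_max_mm:
                    offsets.append(((di, dj, dk), r))
    return offsets


def _lagged_views(arr: np.ndarray, off):
    sl_a = [slice(None)] * arr.ndim
    sl_b = [slice(None)] * arr.ndim
    for ax, d in enumerate(off):
        if d > 0:
            sl_a[ax] = slice(0, arr.shape[ax] - d)
            sl_b[ax] = slice(d, arr.shape[ax])
        elif d < 0:
            sl_a[ax] = slice(-d, arr.shape[ax])
            sl_b[ax] = slice(0, arr.shape[ax] + d)
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def empirical_acf(
    fields: np.ndarray | list[np.ndarray],
    mask: np.ndarray,
    voxel_mm,
    r_max_mm: float,
):
    """Empirical spatial correlation of standardized field(s) vs mm distance.

    Each field is standardized to zero mean / unit sd within the mask; the
    correlation at each integer-lag offset is the average product over all
    valid in-mask voxel pairs (pooled over fields), and offsets are binned
    by their mm distance.  Returns ``(distances_mm, correlations, weights)``
    with weights the pooled pair counts per bin.
    """
    if isinstance(fields, np.ndarray) and fields.ndim == 3:
        fields = [fields]
    mask = np.asarray(mask, dtype=bool)
    zs = np.empty((len(fields), *mask.shape), dtype=np.float64)
    for i, f in enumerate(fields):
        v = np.asarray(f, dtype=np.float64)
        mv = v[mask]
        sd = mv.std()
        if sd == 0:
            raise ValueError("field is constant within the mask")
        z = np.zeros(mask.shape)
        z[mask] = (mv - mv.mean()) / sd
        zs[i] = z
    offsets = _half_space_offsets(voxel_mm, r_max_mm)
    if not offsets:
        raise ValueError("r_max_mm admits no integer-lag offsets")
    sums: dict[float, float] = {}
    counts: dict[float, int] = {}
    for off, r in offsets:
        key = round(r, 6)
        ma, mb = _lagged_views(mask, off)
        n = int((ma & mb).sum())
        if n == 0:
            continue
        # standardized fields are zero outside the mask, so the plain
        # product sum only accumulates over valid in-mask pairs
        off4 = (0, *off)
        za, zb = _lagged_views(zs, off4)
        sums[key] = sums.get(key, 0.0) + float((za * zb).sum())
        counts[key] = counts.get(key, 0) + n * len(fields)
    dists = np.array(sorted(counts))
    corr = np.array([sums[d] / counts[d] for d in dists])
    weights = np.array([counts[d] for d in dists], dtype=np.float64)
    return dists, corr, weights


def fit_acf_curve(
    dists: np.ndarray,
    corr: np.ndarray,
    weights: np.ndarray | None = None,
    fix_a: float | None = None,
) -> ACFParams:
    """Weighted nonlinear least-squares fit of the mixed ACF to a binned curve.

    Multi-start over a grid of initial points; bounds a in [0, 1],
    b, c in (0.1, 50) mm.  Ties in SSE are broken toward the smallest ``a``
    (the mixed model has identifiability ridges when either component
    vanishes).
    """
    dists = np.asarray(dists, dtype=np.float64)
    corr = np.asarray(corr, dtype=np.float64)
    if len(dists) < 4:
        raise ValueError(f"need at least 4 distance bins to fit, got {len(dists)}")
    w = np.ones_like(dists) if weights is None else np.sqrt(np.asarray(weights, float))
    w = w / w.max()

    def residuals(theta):
        if fix_a is None:
            a, b, c = theta
        else:
            a, (b, c) = fix_a, theta
        model = a * np.exp(-(dists**2) / (2.0 * b**2)) + (1 - a) * np.exp(-dists / c)
        return w * (model - corr)

    lo_bc, hi_bc = 0.1001, 50.0
    starts_a = (0.2, 0.5, 0.8) if fix_a is None else (fix_a,)
    best = None
    for a0 in starts_a:
        for b0 in (2.0, 4.0, 8.0):
            for c0 in (2.0, 6.0, 12.0):
                if fix_a is None:
                    x0 = [a0, b0, c0]
                    bounds = ([0.0, lo_bc, lo_bc], [1.0, hi_bc, hi_bc])
                else:
                    x0 = [b0, c0]
                    bounds = ([lo_bc, lo_bc], [hi_bc, hi_bc])
                try:
                    res = optimize.least_squares(residuals, x0, bounds=bounds)
                except Exception:
                    continue
                sse = float(np.sum(res.fun**2))
                a_fit = fix_a if fix_a is not None else float(res.x[0])
                cand = (sse, a_fit, res.x)
                if best is None or sse < best[0] - 1e-12 or (
                    abs(sse - best[0]) <= 1e-12 and a_fit < best[1]
                ):
                    best = cand
    if best is None:
        raise RuntimeError("ACF fit failed from every starting point")
    if fix_a is None:
        a, b, c = (float(v) for v in best[2])
    else:
        a = float(fix_a)
        b, c = (float(v) for v in best[2])
    return ACFParams(min(max(a, 0.0), 1.0), b, c)


def fit_acf(
    residual: ContrastImage,
    mask: BrainMask,
    r_max_mm: float = 12.0,
    fix_a: float | None = None,
) -> ACFParams:
    """Estimate (a, b, c) from a residual-like scalar field.

    The field is standardized voxelwise within the mask, its empirical
    correlation is computed at every integer-lag offset up to ``r_max_mm``
    and binned by mm distance, and the mixed model is fitted to the binned
    curve by weighted least squares.  ``fix_a=1`` constrains the fit to the
    pure-Gaussian model (used for classical smoothness estimation).
    """
    if r_max_mm <= min(residual.grid.voxel_mm):
        raise ValueError("r_max_mm must exceed the smallest voxel edge")
    dists, corr, weights = empirical_acf(
        residual.values, mask.inside, residual.grid.voxel_mm, r_max_mm
    )
    return fit_acf_curve(dists, corr, weights, fix_a=fix_a)


def dataset_residual_acf(
    dataset: SubjectDataset,
    r_max_mm: float = 12.0,
    fix_a: float | None = None,
) -> ACFParams:
    """Fit the ACF to per-subject residuals (image minus group mean), pooled.

    Pooling the empirical correlations over subjects plays the role of
    averaging smoothness estimates over the sub-bricks of a residual image.
    """
    stacked = dataset.data()
    resid = stacked - stacked.mean(axis=0, keepdims=True)
    fields = [resid[i] for i in range(dataset.n_subjects)]
    dists, corr, weights = empirical_acf(
        fields, dataset.mask.inside, dataset.grid.voxel_mm, r_max_mm
    )
    return fit_acf_curve(dists, corr, weights, fix_a=fix_a)


# ---------------------------------------------------------------------------
# Correlated noise generation
# ---------------------------------------------------------------------------

MAX_CUBE_VOXELS = 4096


def build_covariance(
    params: ACFParams, cube: tuple[int, int, int], voxel_mm
) -> np.ndarray:
    """Pairwise correlation matrix of all voxels in a cube.

    Entry (p, q) is the model ACF at the mm distance between cube voxels p
    and q (row-major voxel order); the diagonal is exactly 1.
    """
    m = int(np.prod(cube))
    if m > MAX_CUBE_VOXELS:
        raise ValueError(
            f"cube {cube} has {m} voxels, exceeding the cap of {MAX_CUBE_VOXELS}; "
            "reduce cube_dims"
        )
    coords = np.indices(cube).reshape(3, m).T.astype(np.float64)
    coords *= np.asarray(voxel_mm)
    d2 = np.zeros((m, m))
    for ax in range(3):
        diff = coords[:, ax : ax + 1] - coords[:, ax]
        d2 += diff**2
    sigma = acf(params, np.sqrt(d2))
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _cholesky_with_jitter(sigma: np.ndarray) -> np.ndarray:
    """Cholesky factor, adding the smallest doubling jitter eps*I if needed."""
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        pass
    eps = 1e-10
    eye = np.eye(sigma.shape[0])
    while eps < 1.0:
        try:
            return np.linalg.cholesky(sigma + eps * eye)
        except np.linalg.LinAlgError:
            eps *= 2.0
    raise np.linalg.LinAlgError("covariance could not be factorized even with jitter")


_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def _cube_cholesky(params: ACFParams, cube: tuple[int, int, int], voxel_mm) -> np.ndarray:
    key = (
        round(params.a, 10),
        round(params.b, 10),
        round(params.c, 10),
        tuple(int(c) for c in cube),
        tuple(round(float(v), 10) for v in voxel_mm),
    )
    L = _CHOL_CACHE.get(key)
    if L is None:
        L = _cholesky_with_jitter(build_covariance(params, cube, voxel_mm))
        if len(_CHOL_CACHE) > 64:  # keep the cache bounded
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = L
    return L


def _generate_noise_batch(
    params: ACFParams,
    grid: VolumeGrid,
    cube_dims: tuple[int, int, int],
    rng: np.random.Generator,
    n_fields: int,
) -> np.ndarray:
    """(n_fields, *grid.dims) unit-variance correlated fields.

    All fields share the cube tiling; each cube factor is applied to all
    fields in one matrix product, which is what makes Monte-Carlo
    calibration loops affordable.
    """
    out = np.empty((n_fields, *grid.dims), dtype=np.float64)
    nx, ny, nz = grid.dims
    cx, cy, cz = cube_dims
    for x0 in range(0, nx, cx):
        for y0 in range(0, ny, cy):
            for z0 in range(0, nz, cz):
                shape = (min(cx, nx - x0), min(cy, ny - y0), min(cz, nz - z0))
                L = _cube_cholesky(params, shape, grid.voxel_mm)
                z = rng.standard_normal((L.shape[0], n_fields))
                vals = (L @ z).T.reshape(n_fields, *shape)
                out[
                    :,
                    x0 : x0 + shape[0],
                    y0 : y0 + shape[1],
                    z0 : z0 + shape[2],
                ] = vals
    return out


def _generate_noise_values(
    params: ACFParams,
    grid: VolumeGrid,
    cube_dims: tuple[int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance correlated field: independent Cholesky cubes tiling the grid."""
    return _generate_noise_batch(params, grid, cube_dims, rng, 1)[0]


def generate_noise(
    params: ACFParams, grid: VolumeGrid, cfg: NoiseInjectionConfig
) -> NoiseField:
    """Generate a unit-variance spatially-autocorrelated Gaussian field.

    The grid's bounding box is tiled by non-overlapping cubes of
    ``cfg.cube_dims`` (edge cubes truncated, each with its own covariance);
    cubes are mutually independent.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    values = _generate_noise_values(params, grid, cfg.cube_dims, rng)
    return NoiseField(grid, values, params, cfg.seed)


def inject_noise(
    dataset: SubjectDataset, params: ACFParams, cfg: NoiseInjectionConfig
) -> SubjectDataset:
    """Add scaled correlated noise to each subject's contrast image.

    Each subject gets an independent field (fresh child seed from
    ``cfg.seed``) whose standard deviation is set to
    ``magnitude_fraction x mean(|contrast|)`` over that subject's in-mask
    voxels — "100% of the mean contrast strength" at the default fraction 1.
    The mask is unchanged.  All-zero images get a warning and no noise.
    """
    mask = dataset.mask.inside
    children = np.random.SeedSequence(cfg.seed).spawn(dataset.n_subjects)
    images = []
    for img, ss in zip(dataset.images, children):
        scale = cfg.magnitude_fraction * float(
            np.mean(np.abs(img.values[mask]))
        )
        if cfg.magnitude_fraction == 0:
            images.append(img.copy())
            continue
        if scale == 0:
            warnings.warn(
                "all-zero contrast image: noise scale is 0, skipping injection",
                stacklevel=2,
            )
            images.append(img.copy())
            continue
        rng = np.random.default_rng(ss)
        noise = _generate_noise_values(params, dataset.grid, cfg.cube_dims, rng)
        images.append(ContrastImage(dataset.grid, img.values + scale * noise))
    return SubjectDataset(images, dataset.mask)
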