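"""Volumetric image I/O and lattice geometry.

All computations in this package live on a regular 3D lattice.  Physical
distances are Euclidean distances of voxel-index differences scaled by the
voxel edge lengths in millimetres; image orientation and affine handedness
play no role in any statistic computed here, so volumes are written with a
plain diagonal (scaling) affine and the affine of files read from disk is
not interpreted beyond its voxel sizes.

Non-finite voxel values are tolerated outside the analysis mask (real
first-level contrast images carry NaN outside the brain) and are ignored by
every downstream statistic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "ContrastImage",
    "BrainMask",
    "SubjectDataset",
    "read_volume",
    "read_mask",
    "write_volume",
    "intersect_mask",
]

IntTriple = tuple[int, int, int]
FloatTriple = tuple[float, float, float]


@dataclass(frozen=True)
class VolumeGrid:
    """Image lattice: voxel counts per axis and voxel edge lengths in mm."""

    dims: IntTriple
    voxel_mm: FloatTriple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(dims) != 3 or len(voxel_mm) != 3:
            raise ValueError("VolumeGrid is strictly three-dimensional")
        if any(d < 1 for d in dims):
            raise ValueError(f"all dims must be >= 1, got {dims}")
        if any(v <= 0 for v in voxel_mm):
            raise ValueError(f"all voxel sizes must be > 0 mm, got {voxel_mm}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_mm", voxel_mm)

    @property
    def shape(self) -> IntTriple:
        return self.dims

    @property
    def n_voxels(self) -> int:
        """Total voxel count (product of the axis dimensions)."""
        nx, ny, nz = self.dims
        return nx * ny * nz

    def affine(self) -> np.ndarray:
        """Diagonal scaling affine encoding the voxel sizes."""
        return np.diag([*self.voxel_mm, 1.0])


def _check_shape(grid: VolumeGrid, values: np.ndarray, what: str) -> None:
    if tuple(values.shape) != grid.dims:
        raise ValueError(
            f"{what} shape {tuple(values.shape)} does not match grid dims {grid.dims}"
        )


@dataclass
class ContrastImage:
    """A scalar 3D field (contrast units) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_shape(self.grid, self.values, "image")

    def copy(self) -> "ContrastImage":
        return ContrastImage(self.grid, self.values.copy())


@dataclass
class BrainMask:
    """Boolean analysis mask on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        _check_shape(self.grid, self.inside, "mask")
        if not self.inside.any():
            raise ValueError("mask contains no inside voxels")

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())


@dataclass
class SubjectDataset:
    """Per-subject contrast images sharing one grid and analysis mask."""

    images: list[ContrastImage]
    mask: BrainMask

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("a dataset needs at least two subjects")
        for img in self.images:
            if img.grid != self.mask.grid:
                raise ValueError("all images must share the mask's grid")

    @property
    def n_subjects(self) -> int:
        return len(self.images)

    @property
    def grid(self) -> VolumeGrid:
        return self.mask.grid

    def data(self) -> np.ndarray:
        """Stack subject values into an (n_subjects, nx, ny, nz) array."""
        return np.stack([img.values for img in self.images])

    def with_images(self, stacked: np.ndarray) -> "SubjectDataset":
        """New dataset with the same grid/mask and the given stacked values."""
        imgs = [ContrastImage(self.grid, stacked[i]) for i in range(stacked.shape[0])]
        return SubjectDataset(imgs, self.mask)


def read_volume(path: str | Path) -> ContrastImage:
    """Read a single-volume 3D NIfTI file.

    Voxel sizes are taken from the header pixel dimensions.  4D files and
    non-positive pixel dimensions are rejected.
    """
    try:
        nifti = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"could not read NIfTI volume {path!r}: {exc}") from exc
    shape = nifti.shape
    if len(shape) != 3:
        raise ValueError(
            f"expected a 3D single-volume image, got {len(shape)}D data "
            f"with shape {tuple(shape)} in {path!r}"
        )
    zooms = tuple(float(z) for z in nifti.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive pixel dimensions {zooms} in {path!r}")
    grid = VolumeGrid(tuple(int(s) for s in shape), zooms)
    values = np.asarray(nifti.dataobj, dtype=np.float64)
    return ContrastImage(grid, values)


def read_mask(path: str | Path, threshold: float = 0.5) -> BrainMask:
    """Read a NIfTI volume and binarize it (values > ``threshold`` inside)."""
    img = read_volume(path)
    inside = np.nan_to_num(img.values, nan=0.0) > threshold
    return BrainMask(img.grid, inside)


def write_volume(img: ContrastImage | BrainMask, path: str | Path) -> None:
    """Write a volume (or a boolean mask as 0/1) as a NIfTI-1 file."""
    if isinstance(img, BrainMask):
        values = img.inside.astype(np.uint8)
        grid = img.grid
    else:
        values = img.values
        grid = img.grid
    nifti = nib.Nifti1Image(values, grid.affine())
    nifti.header.set_zooms(grid.voxel_mm)
    path = Path(path)
    if not path.parent.exists():
        raise ValueError(f"parent directory {path.parent} does not exist")
    nib.save(nifti, str(path))


def intersect_mask(
    images: Sequence[ContrastImage],
    policy: str = "all_finite_nonzero",
) -> BrainMask:
    """Build an analysis mask from per-subject images.

    A voxel is inside iff every subject satisfies the policy there:
    ``all_finite_nonzero`` requires a finite nonzero value, ``all_finite``
    only a finite value.  Raises if the resulting mask is empty.
    """
    if len(images) < 1:
        raise ValueError("need at least one image")
    if policy not in ("all_finite_nonzero", "all_finite"):
        raise ValueError(f"unknown mask policy {policy!r}")
    grid = images[0].grid
    inside = np.ones(grid.dims, dtype=bool)
    for img in images:
        if img.grid != grid:
            raise ValueError("images do not share a grid")
        ok = np.isfinite(img.values)
        if policy == "all_finite_nonzero":
            ok &= img.values != 0
        inside &= ok
    if not inside.any():
        raise ValueError("mask intersection is empty")
    return BrainMask(grid, inside)
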