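"""Volumetric image container and I/O.

All stages of the pipeline exchange data through :class:`VoxelGrid`, a 3D
scalar array with voxel spacing and a world origin, both in micrometres.
World coordinates are defined at voxel centers::

    world(i, j, k) = origin_um + (i, j, k) * spacing_um

NIfTI-1 headers store spacing in millimetres; the conversion happens on
load/save so that everything in memory is µm.  Multi-page TIFF stacks carry
no reliable 3D spacing, so it must be supplied by the caller.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from nibabel import orientations as _ornt

__all__ = ["VoxelGrid", "read_volume", "write_volume", "downsample", "orient_to_standard"]

_MM_TO_UM = 1000.0


@dataclasses.dataclass
class VoxelGrid:
    """A 3D scalar image with world geometry in micrometres."""

    data: np.ndarray
    spacing_um: np.ndarray
    origin_um: np.ndarray
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_um = np.asarray(self.spacing_um, dtype=float).reshape(3)
        self.origin_um = np.asarray(self.origin_um, dtype=float).reshape(3)
        if np.any(self.spacing_um <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Map world µm coordinates to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return (pts - self.origin_um) / self.spacing_um

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin_um + idx * self.spacing_um

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_um, other.spacing_um, atol=atol)
            and np.allclose(self.origin_um, other.origin_um, atol=atol)
        )

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry but different voxel data."""
        return VoxelGrid(data, self.spacing_um.copy(), self.origin_um.copy(), self.axis_codes)


def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing_um / _MM_TO_UM)
    aff[:3, 3] = grid.origin_um / _MM_TO_UM
    return aff


def read_volume(path: str | Path, spacing_um=None, origin_um=(0.0, 0.0, 0.0)) -> VoxelGrid:
    """Read a NIfTI-1 volume or a multi-page TIFF stack.

    TIFF stacks have no trustworthy 3D spacing metadata, so ``spacing_um``
    is required for them.  For NIfTI, spacing/origin come from the header
    (mm, converted to µm).
    """
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        if spacing_um is None:
            raise ValueError("TIFF stacks require an explicit spacing_um")
        pages = tifffile.imread(path)
        # tifffile returns (pages, rows, cols); reorder to (x, y, z) with
        # z the page axis so index order matches NIfTI volumes.
        data = np.moveaxis(pages, 0, -1) if pages.ndim == 3 else pages[..., None]
        return VoxelGrid(data, spacing_um, origin_um)
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float) * _MM_TO_UM
    if np.any(zooms <= 0):
        raise ValueError(f"non-positive spacing in NIfTI header: {zooms}")
    origin = np.asarray(img.affine[:3, 3], dtype=float) * _MM_TO_UM
    data = np.asanyarray(img.dataobj)
    return VoxelGrid(data, zooms, origin)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as NIfTI-1 (or TIFF when the suffix asks for it)."""
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.moveaxis(grid.data, -1, 0))
        return
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine_from_grid(grid))
    img.header.set_zooms(tuple(grid.spacing_um / _MM_TO_UM))
    nib.save(img, str(path))


def downsample(grid: VoxelGrid, factor: int) -> VoxelGrid:
    """Block-mean downsampling by an integer factor.

    Output shape is ``ceil(shape / factor)``; edge blocks that extend past
    the volume average only the voxels they contain.  Spacing is multiplied
    by the factor so world extent is preserved.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return grid.like(grid.data.copy())
    data = grid.data.astype(float)
    out_shape = tuple(-(-s // factor) for s in data.shape)
    out = np.zeros(out_shape)
    for i in range(out_shape[0]):
        for j in range(out_shape[1]):
            for k in range(out_shape[2]):
                block = data[
                    i * factor : (i + 1) * factor,
                    j * factor : (j + 1) * factor,
                    k * factor : (k + 1) * factor,
                ]
                out[i, j, k] = block.mean()
    new_origin = grid.origin_um + (factor - 1) / 2.0 * grid.spacing_um
    return VoxelGrid(out, grid.spacing_um * factor, new_origin, grid.axis_codes)


def orient_to_standard(grid: VoxelGrid, target_codes) -> VoxelGrid:
    """Reorient by pure axis permutation/flips to the requested axis codes.

    Voxel values are untouched as a multiset; the world position of any
    anatomical point is preserved by updating origin and spacing order.
    """
    target = tuple(str(c).upper() for c in target_codes)
    current = tuple(str(c).upper() for c in grid.axis_codes)
    axis_of = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}
    for codes in (target, current):
        if len(codes) != 3 or any(c not in axis_of for c in codes):
            raise ValueError(f"invalid axis codes {codes}")
        if len({axis_of[c] for c in codes}) != 3:
            raise ValueError(f"axis codes {codes} do not span three distinct axes")
    try:
        cur_ornt = _ornt.axcodes2ornt(current)
        tgt_ornt = _ornt.axcodes2ornt(target)
    except Exception as exc:  # pragma: no cover - nibabel raises assorted types
        raise ValueError(f"invalid axis codes {current} -> {target}") from exc
    if np.any(np.isnan(cur_ornt)) or np.any(np.isnan(tgt_ornt)):
        raise ValueError(f"invalid axis codes {current} -> {target}")
    transform = _ornt.ornt_transform(cur_ornt, tgt_ornt)
    new_data = _ornt.apply_orientation(grid.data, transform)
    perm = transform[:, 0].astype(int)
    new_spacing = grid.spacing_um[perm]
    # Axes are permuted; a flip simultaneously reverses the data axis and
    # the anatomical code, so each voxel keeps its anatomical location.
    new_origin = grid.origin_um[perm]
    return VoxelGrid(new_data, new_spacing, new_origin, target)
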