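"""Volumetric data model: grids, affines, volumetry, hemispheric flipping.

All world coordinates are RAS millimetres. Voxel indices are 0-based and a
voxel *contains* the world point of its centre. Grids used for group analysis
share one template lattice whose midsagittal plane is the world plane x=0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "DisplacementField",
    "read_volume",
    "write_volume",
    "mask_volume_ml",
    "flip_to_right",
    "apply_displacement",
]

_AFFINE_ATOL = 1e-6


@dataclass
class VolumeGrid:
    """A 3D scalar or binary image with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values. Binary grids hold only {0, 1}.
    affine : ndarray, shape (4, 4)
        Homogeneous transform mapping 0-based voxel indices to world mm.
    space_tag : str
        Free-text label of the coordinate space (e.g. ``"template"``).
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"VolumeGrid requires 3D data, got {self.data.ndim}D"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def is_binary(self) -> bool:
        vals = np.unique(self.data)
        return bool(np.isin(vals, (0, 1)).all())

    def voxel_to_world(self, idx) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Map world mm coordinates (..., 3) to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_world(self, xyz) -> np.ndarray:
        """True where the (rounded) voxel index of a world point is in bounds."""
        v = np.round(self.world_to_voxel(xyz)).astype(int)
        v = np.atleast_2d(v)
        ok = np.all((v >= 0) & (v < np.array(self.shape)), axis=-1)
        return ok if ok.size > 1 else bool(ok[0])

    def same_lattice(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_AFFINE_ATOL
        )

    def require_same_lattice(self, other: "VolumeGrid", what: str = "grids") -> None:
        if not self.same_lattice(other):
            raise ValueError(
                f"{what} must share one lattice: shapes {self.shape} vs "
                f"{other.shape} or affines differ beyond {_AFFINE_ATOL}"
            )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return replace(self, data=data)


@dataclass
class DisplacementField:
    """Per-voxel world-mm displacement vectors on a grid lattice.

    ``vectors`` has shape ``grid.shape + (3,)``; component order (x, y, z) in mm.
    """

    vectors: np.ndarray
    affine: np.ndarray
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement field contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)


def read_volume(path, space_tag: str = "template") -> VolumeGrid:
    """Read a 3D NIfTI-1 volume.

    Rejects non-3D images; use :func:`read_displacement_field` for 4D vector
    fields.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D volume, got {data.ndim}D data in {path}"
        )
    return VolumeGrid(data=data, affine=np.asarray(img.affine), space_tag=space_tag)


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a grid as NIfTI-1 (.nii or .nii.gz); lossless for data and affine."""
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, grid.affine)
    # qform+sform both set so the affine survives round-trips exactly
    img.set_sform(grid.affine, code=2)
    img.set_qform(None)
    nib.save(img, str(path))


def read_displacement_field(path, space_tag: str = "template") -> DisplacementField:
    """Read a displacement field stored as 4D NIfTI with the vector axis last."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"expected 4D (x,y,z,3) displacement field, got shape {data.shape}"
        )
    return DisplacementField(vectors=data, affine=np.asarray(img.affine), space_tag=space_tag)


def write_displacement_field(fld: DisplacementField, path) -> None:
    img = nib.Nifti1Image(fld.vectors.astype(np.float32), fld.affine)
    nib.save(img, str(path))


def _require_binary(grid: VolumeGrid, op: str) -> None:
    if not grid.is_binary():
        raise ValueError(f"{op} requires a binary mask (values in {{0,1}})")


def mask_volume_ml(mask: VolumeGrid) -> float:
    """Volume of a binary mask in millilitres.

    (number of 1-voxels) x |det(affine[:3,:3])| / 1000.
    """
    _require_binary(mask, "mask_volume_ml")
    n = int(np.count_nonzero(mask.data))
    return n * mask.voxel_volume_mm3 / 1000.0


def _x_axis_world(grid: VolumeGrid) -> np.ndarray:
    """World x-coordinates of voxel centres along index axis 0."""
    nx = grid.shape[0]
    return grid.affine[0, 0] * np.arange(nx) + grid.affine[0, 3]


def _check_midsagittal_symmetry(grid: VolumeGrid) -> None:
    a = grid.affine
    if not (abs(a[0, 1]) < _AFFINE_ATOL and abs(a[0, 2]) < _AFFINE_ATOL
            and abs(a[1, 0]) < _AFFINE_ATOL and abs(a[2, 0]) < _AFFINE_ATOL):
        raise ValueError(
            "flip_to_right requires the first index axis aligned with world x"
        )
    xs = _x_axis_world(grid)
    if not np.allclose(xs, -xs[::-1], atol=_AFFINE_ATOL):
        raise ValueError(
            "grid has no midsagittal symmetry plane: voxel-centre x coordinates "
            "are not mirror-symmetric about world x=0"
        )


def flip_to_right(mask: VolumeGrid) -> VolumeGrid:
    """Project a binary mask onto the right hemisphere (world x >= 0).

    Content at world x < 0 is reflected through the midsagittal plane and
    united with the content already at x >= 0; the left half of the output is
    empty. Requires a grid whose voxel-centre layout is mirror-symmetric about
    x = 0 (the synthetic template guarantees this), so reflection is an exact
    array reversal along the first index axis.
    """
    _require_binary(mask, "flip_to_right")
    _check_midsagittal_symmetry(mask)
    data = mask.data.astype(bool)
    reflected = data[::-1, :, :]
    right = _x_axis_world(mask) >= 0
    out = np.zeros_like(data)
    out[right] = data[right] | reflected[right]
    return mask.with_data(out.astype(np.uint8))


def apply_displacement(
    grid: VolumeGrid,
    fld: DisplacementField,
    interpolation: str = "linear",
) -> VolumeGrid:
    """Resample ``grid`` through a displacement field on the same lattice.

    output(v) = grid sampled at world(v) + field(v). Use ``nearest`` for
    binary masks and label volumes, ``linear`` for scalar images.
    """
    if fld.vectors.shape[:3] != grid.shape:
        raise ValueError(
            f"shape mismatch: field {fld.vectors.shape[:3]} vs grid {grid.shape}"
        )
    if interpolation not in ("nearest", "linear"):
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij"), axis=-1
    )
    world = grid.voxel_to_world(idx.reshape(-1, 3)) + fld.vectors.reshape(-1, 3)
    sample = grid.world_to_voxel(world)
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        grid.data.astype(float), sample.T, order=order, mode="constant", cval=0.0
    ).reshape(grid.shape)
    if interpolation == "nearest":
        out = out.astype(grid.data.dtype)
    return grid.with_data(out)
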