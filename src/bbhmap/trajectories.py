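"""Stereotactic trajectory geometry: capsule masks, lengths, target labels,
overlap frequency maps.

A trajectory is the straight entry-point -> target-point segment in template
mm. Its rasterized mask is a *capsule*: every voxel whose centre lies within
radius r = (diameter_voxels / 2) * voxel_size of the segment, with rounded
(hemispherical) end caps, matching the common 10-voxel-diameter convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import VolumeGrid

__all__ = [
    "TrajectorySpec",
    "trajectory_length_mm",
    "rasterize_trajectory",
    "classify_target",
    "overlap_frequency_map",
]

_MIN_LENGTH_MM = 1e-6


@dataclass(frozen=True)
class TrajectorySpec:
    """Entry and target point of one biopsy trajectory, in template mm."""

    entry_mm: tuple[float, float, float]
    target_mm: tuple[float, float, float]
    diameter_voxels: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry_mm", tuple(float(v) for v in self.entry_mm))
        object.__setattr__(self, "target_mm", tuple(float(v) for v in self.target_mm))
        if self.diameter_voxels < 1:
            raise ValueError("diameter_voxels must be >= 1")
        if np.linalg.norm(np.subtract(self.target_mm, self.entry_mm)) < _MIN_LENGTH_MM:
            raise ValueError("entry and target points coincide (zero-length trajectory)")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry to target."""
        d = np.subtract(self.target_mm, self.entry_mm)
        return d / np.linalg.norm(d)


def trajectory_length_mm(spec: TrajectorySpec) -> float:
    """Euclidean entry-to-target distance in mm."""
    return float(np.linalg.norm(np.subtract(spec.target_mm, spec.entry_mm)))


def _isotropic_spacing(grid: VolumeGrid) -> float:
    spac = np.linalg.norm(grid.affine[:3, :3], axis=0)
    if not np.allclose(spac, spac[0], rtol=1e-6):
        raise ValueError(
            "capsule rasterization requires isotropic voxels, "
            f"got spacings {spac}"
        )
    return float(spac[0])


def segment_point_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point (n,3) to the segment a->b."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def rasterize_trajectory(spec: TrajectorySpec, grid: VolumeGrid) -> VolumeGrid:
    """Binary capsule mask of the trajectory on the given lattice.

    Includes every voxel whose centre is within
    r = (diameter_voxels/2) * voxel_size of the entry->target segment
    (inclusive comparison). Both endpoints must lie inside the grid.
    """
    spacing = _isotropic_spacing(grid)
    a = np.asarray(spec.entry_mm, dtype=float)
    b = np.asarray(spec.target_mm, dtype=float)
    for name, p in (("entry", a), ("target", b)):
        if not grid.contains_world(p):
            raise ValueError(f"{name} point {tuple(p)} lies outside the grid")
    r = spec.diameter_voxels / 2.0 * spacing

    # bounding box in voxel space, padded by the radius
    corners_v = grid.world_to_voxel(np.stack([a, b]))
    pad = r / spacing + 1.0
    lo = np.maximum(np.floor(corners_v.min(axis=0) - pad).astype(int), 0)
    hi = np.minimum(np.ceil(corners_v.max(axis=0) + pad).astype(int) + 1,
                    np.array(grid.shape))

    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    centres = grid.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    inside = segment_point_distance(centres, a, b) <= r

    out = np.zeros(grid.shape, dtype=np.uint8)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside.reshape(ii.shape)
    return VolumeGrid(out, grid.affine, grid.space_tag)


def classify_target(
    target_mm,
    atlas: VolumeGrid,
    search_radius_mm: float = 3.0,
) -> str | int:
    """Atlas label at a target point.

    Returns the label at the containing voxel; if that voxel is background
    (0), the modal non-zero label within ``search_radius_mm``; if still none,
    the string ``"unclassified"``. This radius fallback stands in for manual
    review of points the atlas leaves unlabelled.
    """
    v = np.round(atlas.world_to_voxel(np.asarray(target_mm, float))).astype(int)
    if np.any(v < 0) or np.any(v >= np.array(atlas.shape)):
        raise ValueError(f"target point {tuple(target_mm)} lies outside the grid")
    label = int(atlas.data[tuple(v)])
    if label != 0:
        return label

    spac = np.linalg.norm(atlas.affine[:3, :3], axis=0)
    rad_vox = np.maximum(np.ceil(search_radius_mm / spac).astype(int), 0)
    lo = np.maximum(v - rad_vox, 0)
    hi = np.minimum(v + rad_vox + 1, np.array(atlas.shape))
    sub = atlas.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    centres = atlas.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    dist = np.linalg.norm(centres - np.asarray(target_mm, float), axis=1)
    labels = sub.reshape(-1)
    near = (dist <= search_radius_mm) & (labels != 0)
    if not near.any():
        return "unclassified"
    vals, counts = np.unique(labels[near], return_counts=True)
    # ties broken by smaller label id for determinism
    return int(vals[np.argmax(counts)])


def overlap_frequency_map(masks: list[VolumeGrid]) -> VolumeGrid:
    """Per-voxel count of how many binary masks contain the voxel."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    acc = np.zeros(first.shape, dtype=np.int16)
    for m in masks:
        first.require_same_lattice(m, "frequency-map inputs")
        if not m.is_binary():
            raise ValueError("overlap_frequency_map requires binary masks")
        acc += m.data.astype(np.int16)
    return VolumeGrid(acc, first.affine, first.space_tag)
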