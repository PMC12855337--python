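"""Hemorrhage frequency along a standardized biopsy trajectory.

Every subject's trajectory is rescaled to a unit axis (0 = entry point,
1 = target point); each hemorrhage voxel is expressed as (axial fraction,
radial distance) relative to that subject's own trajectory, then pooled.
Axial fractions slightly outside [0, 1] are kept up to [-0.2, 1.2] because
bleeds extend past the needle tip; truncating them would bias the distal
peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import VolumeGrid
from .trajectories import TrajectorySpec, trajectory_length_mm

__all__ = [
    "AxisProfile",
    "to_trajectory_frame",
    "axial_profile",
    "cross_section_map",
]

AXIAL_RANGE = (-0.2, 1.2)


@dataclass
class AxisProfile:
    """Pooled hemorrhage frequency along the standardized trajectory."""

    edges: np.ndarray            # bin edges on the axial fraction, increasing
    counts_per_bin: np.ndarray   # hemorrhage voxels per bin, all subjects
    subjects_per_bin: np.ndarray  # subjects contributing >= 1 voxel per bin
    n_excluded_radial: int       # voxels beyond the radial cap
    n_excluded_axial: int        # voxels outside the retained axial range

    @property
    def n_bins(self) -> int:
        return len(self.counts_per_bin)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def argmax_fraction(self) -> float:
        """Axial fraction of the most frequent bin (centre)."""
        return float(self.centers[int(np.argmax(self.counts_per_bin))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.edges[:-1],
                "bin_end": self.edges[1:],
                "voxel_count": self.counts_per_bin,
                "subject_count": self.subjects_per_bin,
            }
        )


def to_trajectory_frame(point_mm, spec: TrajectorySpec) -> tuple[float, float]:
    """(axial fraction, radial mm) of a world point in a trajectory's frame."""
    a, r = _frame_coords(np.atleast_2d(np.asarray(point_mm, float)), spec)
    return float(a[0]), float(r[0])


def _frame_coords(points: np.ndarray, spec: TrajectorySpec):
    entry = np.asarray(spec.entry_mm, float)
    length = trajectory_length_mm(spec)
    u = spec.direction
    rel = points - entry
    axial_mm = rel @ u
    radial = np.linalg.norm(rel - np.outer(axial_mm, u), axis=1)
    return axial_mm / length, radial


def axial_profile(
    bbh_masks: list[VolumeGrid],
    specs: list[TrajectorySpec],
    n_bins: int = 24,
    radial_cap_mm: float = 20.0,
) -> AxisProfile:
    """Pool hemorrhage voxels of all subjects into axial-fraction bins."""
    if len(bbh_masks) != len(specs):
        raise ValueError(
            f"got {len(bbh_masks)} masks but {len(specs)} trajectory specs"
        )
    edges = np.linspace(*AXIAL_RANGE, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    subjects = np.zeros(n_bins, dtype=np.int64)
    excl_radial = excl_axial = 0
    for mask, spec in zip(bbh_masks, specs):
        vox = np.argwhere(mask.data)
        if len(vox) == 0:
            continue
        pts = mask.voxel_to_world(vox)
        ax, rad = _frame_coords(pts, spec)
        in_rad = rad <= radial_cap_mm
        excl_radial += int((~in_rad).sum())
        ax = ax[in_rad]
        in_ax = (ax >= edges[0]) & (ax <= edges[-1])
        excl_axial += int((~in_ax).sum())
        ax = ax[in_ax]
        if ax.size == 0:
            continue
        b = np.clip(np.digitize(ax, edges) - 1, 0, n_bins - 1)
        binned = np.bincount(b, minlength=n_bins)
        counts += binned
        subjects += binned > 0
    return AxisProfile(edges, counts, subjects, excl_radial, excl_axial)


def cross_section_map(
    bbh_masks: list[VolumeGrid],
    specs: list[TrajectorySpec],
    at_axial_fraction: float = 1.0,
    half_thickness: float = 0.1,
    grid_mm: float = 30.0,
    n_bins: int = 31,
    radial_cap_mm: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """2D frequency of hemorrhage voxels in a slab perpendicular to the axis.

    The slab is centred at ``at_axial_fraction`` (1.0 = target point). The
    in-plane basis per subject is an arbitrary but deterministic orthonormal
    pair; pooled summaries of the map are rotation-invariant (radial), so the
    orientation convention is harmless. Returns (hist2d, bin_edges_mm).
    """
    if not AXIAL_RANGE[0] <= at_axial_fraction <= AXIAL_RANGE[1]:
        raise ValueError(
            f"at_axial_fraction must lie in [{AXIAL_RANGE[0]}, {AXIAL_RANGE[1]}]"
        )
    if len(bbh_masks) != len(specs):
        raise ValueError("masks and specs differ in length")
    edges = np.linspace(-grid_mm, grid_mm, n_bins + 1)
    hist = np.zeros((n_bins, n_bins), dtype=np.int64)
    total = 0
    for mask, spec in zip(bbh_masks, specs):
        vox = np.argwhere(mask.data)
        if len(vox) == 0:
            continue
        pts = mask.voxel_to_world(vox)
        u = spec.direction
        # deterministic perpendicular pair
        helper = np.array([0.0, 0.0, 1.0])
        if abs(u @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        ax, rad = _frame_coords(pts, spec)
        sel = (np.abs(ax - at_axial_fraction) <= half_thickness) & (rad <= radial_cap_mm)
        if not sel.any():
            continue
        entry = np.asarray(spec.entry_mm, float)
        length = trajectory_length_mm(spec)
        rel = pts[sel] - entry - np.outer(ax[sel] * length, u)
        h, _, _ = np.histogram2d(rel @ e1, rel @ e2, bins=[edges, edges])
        hist += h.astype(np.int64)
        total += int(sel.sum())
    return hist, edges
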