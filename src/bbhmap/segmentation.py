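"""Seed-based hemorrhage segmentation by fast marching.

A front expands from user-supplied seed voxels with a speed that decays with
intensity dissimilarity to the seeds,

    F(v) = 1 / (1 + ((I(v) - I_seed_mean) / sigma_intensity)^2),

and the per-voxel first-arrival time T solves the Eikonal equation
|grad T| = 1/F with a heap-ordered first-order upwind scheme on the
6-connected voxel lattice. Thresholding T yields the hemorrhage mask; this is
the classical semi-automatic fast-marching segmentation workflow. Arrival
times are expressed in voxel-edge units (a unit-speed front crosses one voxel
per unit time), so ``arrival_threshold`` scales with object size in voxels,
not mm.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid, mask_volume_ml

__all__ = [
    "SegmentationParams",
    "fast_marching_arrival",
    "segment_hemorrhage",
    "filter_significant",
    "classify_bbh_location",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the fast-marching segmenter.

    sigma_intensity : intensity-unit scale of the speed falloff; voxels whose
        intensity differs from the seed mean by sigma get speed 1/2.
    arrival_threshold : arrival-time cutoff (voxel-edge units) defining the
        segmented region.
    min_significant_ml : hemorrhages at or above this volume count as
        significant (default 0.5 ml).
    """

    sigma_intensity: float = 100.0
    arrival_threshold: float = 10.0
    min_significant_ml: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_intensity <= 0:
            raise ValueError("sigma_intensity must be > 0")
        if self.arrival_threshold < 0:
            raise ValueError("arrival_threshold must be >= 0")
        if self.min_significant_ml < 0:
            raise ValueError("min_significant_ml must be >= 0")


def speed_map(image: VolumeGrid, seeds: list[tuple[int, int, int]],
              params: SegmentationParams) -> np.ndarray:
    """Front speed at every voxel given the seed mean intensity."""
    img = image.data.astype(float)
    seed_mean = float(np.mean([img[tuple(s)] for s in seeds]))
    return 1.0 / (1.0 + ((img - seed_mean) / params.sigma_intensity) ** 2)


def _check_seeds(image: VolumeGrid, seeds) -> list[tuple[int, int, int]]:
    if seeds is None or len(seeds) == 0:
        raise ValueError("fast marching requires at least one seed voxel")
    shape = np.array(image.shape)
    out = []
    for s in seeds:
        s = tuple(int(v) for v in s)
        if len(s) != 3 or np.any(np.array(s) < 0) or np.any(np.array(s) >= shape):
            raise ValueError(f"seed {s} lies outside the grid {image.shape}")
        out.append(s)
    return out


def _eikonal_update(t_axis: list[float], cost: float) -> float:
    """First-order upwind solution of sum_i (T - t_i)^2 = cost^2.

    ``t_axis`` holds the smallest accepted neighbour time per axis (may be
    empty on some axes). Uses the standard largest-consistent-subset rule.
    """
    ts = sorted(t_axis)
    # try using k smallest neighbour values, largest k whose solution is
    # consistent (T >= all used t_i)
    for k in range(len(ts), 0, -1):
        use = ts[:k]
        s = sum(use)
        s2 = sum(t * t for t in use)
        # k*T^2 - 2*s*T + s2 - cost^2 = 0
        disc = s * s - k * (s2 - cost * cost)
        if disc < 0:
            continue
        t = (s + np.sqrt(disc)) / k
        if t >= use[-1]:
            return float(t)
    return ts[0] + cost


_NEIGH = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def fast_marching_arrival(
    image: VolumeGrid,
    seeds,
    params: SegmentationParams,
) -> VolumeGrid:
    """First-arrival time of an intensity-weighted front from the seeds.

    Returns a float grid; seeds have arrival 0 and all arrivals are finite and
    non-negative. Distances are in voxel-edge units.
    """
    seeds = _check_seeds(image, seeds)
    speed = speed_map(image, seeds, params)
    cost = 1.0 / speed
    shape = image.shape

    T = np.full(shape, np.inf)
    accepted = np.zeros(shape, dtype=bool)
    heap: list[tuple[float, tuple[int, int, int]]] = []
    for s in seeds:
        T[s] = 0.0
        heapq.heappush(heap, (0.0, s))

    nx, ny, nz = shape
    while heap:
        t, v = heapq.heappop(heap)
        if accepted[v] or t > T[v]:
            continue
        accepted[v] = True
        for d in _NEIGH:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if not (0 <= w[0] < nx and 0 <= w[1] < ny and 0 <= w[2] < nz):
                continue
            if accepted[w]:
                continue
            t_axis = []
            for ax in range(3):
                best = np.inf
                for sgn in (-1, 1):
                    u = list(w)
                    u[ax] += sgn
                    u = tuple(u)
                    if 0 <= u[ax] < shape[ax] and accepted[u]:
                        best = min(best, T[u])
                if np.isfinite(best):
                    t_axis.append(best)
            t_new = _eikonal_update(t_axis, cost[w])
            if t_new < T[w]:
                T[w] = t_new
                heapq.heappush(heap, (t_new, w))

    return VolumeGrid(T, image.affine, image.space_tag)


def segment_hemorrhage(
    image: VolumeGrid,
    seeds,
    params: SegmentationParams,
) -> VolumeGrid:
    """Binary hemorrhage mask: arrival <= threshold, connected to the seeds."""
    seeds = _check_seeds(image, seeds)
    arrival = fast_marching_arrival(image, seeds, params)
    below = arrival.data <= params.arrival_threshold
    labels, _ = ndimage.label(below, structure=ndimage.generate_binary_structure(3, 1))
    keep = {labels[s] for s in seeds if below[s]}
    keep.discard(0)
    mask = np.isin(labels, sorted(keep)) if keep else np.zeros_like(below)
    if not mask.any():
        warnings.warn(
            "segmentation produced an empty mask (threshold too small?)",
            stacklevel=2,
        )
    return VolumeGrid(mask.astype(np.uint8), image.affine, image.space_tag)


def filter_significant(
    mask: VolumeGrid, params: SegmentationParams
) -> tuple[bool, float]:
    """Volume of a hemorrhage mask and whether it reaches significance.

    Significance is inclusive: exactly ``min_significant_ml`` counts.
    """
    vol = mask_volume_ml(mask)
    return vol >= params.min_significant_ml, vol


def classify_bbh_location(
    bbh_mask: VolumeGrid,
    lesion_mask: VolumeGrid,
    trajectory_mask: VolumeGrid | None = None,
) -> str:
    """Classify a hemorrhage as intralesional, extralesional or both.

    Intralesional if >= 90% of hemorrhage voxels fall inside the lesion,
    extralesional if <= 10%, otherwise both. The trajectory mask is accepted
    for lattice validation (extralesional bleeds track the needle path) but
    the categorisation itself depends only on the lesion overlap.
    """
    bbh_mask.require_same_lattice(lesion_mask, "hemorrhage and lesion masks")
    if trajectory_mask is not None:
        bbh_mask.require_same_lattice(trajectory_mask, "hemorrhage and trajectory masks")
    b = bbh_mask.data.astype(bool)
    n = int(b.sum())
    if n == 0:
        raise ValueError("empty hemorrhage mask cannot be classified")
    frac = float((b & lesion_mask.data.astype(bool)).sum()) / n
    if frac >= 0.9:
        return "intralesional"
    if frac <= 0.1:
        return "extralesional"
    return "both"
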