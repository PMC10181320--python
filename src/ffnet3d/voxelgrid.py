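"""Adaptive voxelization and the point↔voxel scatter/gather primitives.

The grid adapts to the cloud: the voxel edge is fixed by the longest
bounding-box axis divided by a target voxel count, so a seedling and the
same plant weeks later occupy the grid at comparable resolution.  Cells are
cubic and half-open ``[lo, hi)``; a point exactly on the global max corner
clamps into the last cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, gather_rows, segment_max
from .io import LabeledPointCloud

__all__ = [
    "GridSpec",
    "VoxelAssignment",
    "SparseGrid",
    "fit_grid",
    "assign",
    "scatter_max",
    "scatter_mean",
    "gather",
    "coarsen",
    "majority_labels",
]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: min corner, per-axis voxel size, dims."""

    origin: np.ndarray
    voxel_size: np.ndarray
    dims: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "voxel_size",
                           np.asarray(self.voxel_size, float))
        object.__setattr__(self, "dims", np.asarray(self.dims, np.int64))
        if (self.voxel_size <= 0).any():
            raise ValueError("voxel_size components must be > 0")
        if (self.dims < 1).any():
            raise ValueError("dims components must be ≥ 1")

    def covers(self, coords: np.ndarray) -> bool:
        hi = self.origin + self.dims * self.voxel_size
        return bool(
            (coords >= self.origin - 1e-9).all() and (coords <= hi + 1e-9).all()
        )


@dataclass
class VoxelAssignment:
    """Point→voxel mapping over the deduplicated, sorted active-voxel list."""

    spec: GridSpec
    point_to_voxel: np.ndarray  # N ints indexing active_coords rows
    active_coords: np.ndarray   # M×3 ints, unique, lexicographically sorted
    counts: np.ndarray          # M ints, points per active voxel

    @property
    def n_points(self) -> int:
        return self.point_to_voxel.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.active_coords.shape[0]


@dataclass
class SparseGrid:
    """Active voxel coordinates plus per-voxel features at one level."""

    coords: np.ndarray      # M×3 ints
    features: Tensor        # M×C
    spec: GridSpec
    level: int = 0

    def __post_init__(self):
        if self.coords.shape[0] != self.features.data.shape[0]:
            raise ValueError("features row count must match coords")


def fit_grid(
    cloud: LabeledPointCloud | np.ndarray,
    target_longest_axis_voxels: int = 128,
    pad: float = 0.0,
) -> GridSpec:
    """Cubic grid whose longest bounding-box axis spans a fixed voxel count.

    Scale-adaptive: scaling the cloud rescales the voxel edge so occupancy
    patterns are identical.
    """
    if target_longest_axis_voxels < 2:
        raise ValueError("target_longest_axis_voxels must be ≥ 2")
    coords = cloud.coords if isinstance(cloud, LabeledPointCloud) else cloud
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    extent = hi - lo
    longest = float(extent.max())
    if longest <= 0:
        raise ValueError("degenerate cloud: zero extent on every axis")
    edge = longest / target_longest_axis_voxels
    dims = np.maximum(np.ceil(extent / edge - 1e-9).astype(np.int64), 1)
    return GridSpec(origin=lo, voxel_size=np.full(3, edge), dims=dims)


def assign(
    cloud: LabeledPointCloud | np.ndarray, spec: GridSpec
) -> VoxelAssignment:
    """Group points by the half-open voxel cell they occupy."""
    coords = cloud.coords if isinstance(cloud, LabeledPointCloud) else cloud
    idx = np.floor((coords - spec.origin) / spec.voxel_size).astype(np.int64)
    # max-corner clamp: a point exactly on the far face belongs to the last cell
    over = idx >= spec.dims
    on_face = np.isclose(
        coords, spec.origin + idx * spec.voxel_size, rtol=0, atol=1e-9
    )
    idx = np.where(over & on_face, idx - 1, idx)
    if (idx < 0).any() or (idx >= spec.dims).any():
        raise ValueError("point outside the grid's padded box")
    active, inverse, counts = np.unique(
        idx, axis=0, return_inverse=True, return_counts=True
    )
    return VoxelAssignment(
        spec=spec,
        point_to_voxel=inverse.astype(np.int64),
        active_coords=active,
        counts=counts.astype(np.int64),
    )


def scatter_max(point_features, assignment: VoxelAssignment) -> Tensor:
    """Per-voxel elementwise max over member points (order-invariant)."""
    x = point_features if isinstance(point_features, Tensor) \
        else Tensor(point_features)
    if x.data.shape[0] != assignment.n_points:
        raise ValueError("feature row count must match assignment")
    return segment_max(x, assignment.point_to_voxel, assignment.n_voxels)


def scatter_mean(point_features, assignment: VoxelAssignment) -> Tensor:
    """Per-voxel mean over member points (configurable alternative to max)."""
    from .autodiff import scatter_add_rows

    x = point_features if isinstance(point_features, Tensor) \
        else Tensor(point_features)
    if x.data.shape[0] != assignment.n_points:
        raise ValueError("feature row count must match assignment")
    summed = scatter_add_rows(x, assignment.point_to_voxel,
                              assignment.n_voxels)
    return summed * (1.0 / assignment.counts)[:, None]


def gather(voxel_features, assignment: VoxelAssignment) -> Tensor:
    """Broadcast each voxel's feature row to its member points."""
    x = voxel_features if isinstance(voxel_features, Tensor) \
        else Tensor(voxel_features)
    if x.data.shape[0] != assignment.n_voxels:
        raise ValueError("feature row count must match active voxel count")
    return gather_rows(x, assignment.point_to_voxel)


def coarsen(assignment: VoxelAssignment, factor: int) -> VoxelAssignment:
    """Integer-divide voxel coordinates; merge points accordingly."""
    if factor < 2:
        raise ValueError("factor must be ≥ 2")
    coarse = assignment.active_coords // factor
    active, inverse = np.unique(coarse, axis=0, return_inverse=True)
    p2v = inverse[assignment.point_to_voxel]
    counts = np.bincount(p2v, minlength=active.shape[0]).astype(np.int64)
    spec = assignment.spec
    new_spec = GridSpec(
        origin=spec.origin,
        voxel_size=spec.voxel_size * factor,
        dims=-(-spec.dims // factor),
    )
    return VoxelAssignment(
        spec=new_spec,
        point_to_voxel=p2v.astype(np.int64),
        active_coords=active,
        counts=counts,
    )


def majority_labels(
    labels: np.ndarray, assignment: VoxelAssignment, num_classes: int
) -> np.ndarray:
    """Per-voxel majority vote over member-point labels; ties → smaller id."""
    votes = np.zeros((assignment.n_voxels, num_classes), dtype=np.int64)
    np.add.at(votes, (assignment.point_to_voxel, labels), 1)
    return votes.argmax(axis=1)
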