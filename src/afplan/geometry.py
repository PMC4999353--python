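"""Voxel grids, binary masks, and exact ray-grid traversal.

All spatial quantities are in millimetres in an LPS-like frame:
+x patient-left, +y patient-posterior, +z patient-superior.  Voxel
indices are 0-based and the world coordinate of a voxel *center* is
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VoxelGrid:
    """A regular axis-aligned voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing_mm : tuple of float
        Voxel pitch along each axis, strictly positive.
    origin_mm : tuple of float
        World coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size (mm) spanned by voxel centers plus one voxel."""
        return np.asarray(self.shape) * np.asarray(self.spacing_mm)

    def world_coords(self, dtype=np.float64) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis arrays of voxel-center world coordinates."""
        o = np.asarray(self.origin_mm)
        sp = np.asarray(self.spacing_mm)
        return tuple(
            (o[i] + sp[i] * np.arange(self.shape[i], dtype=dtype)) for i in range(3)
        )

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (N, 3) of voxel index triples (N, 3)."""
        idx = np.atleast_2d(np.asarray(indices))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def index_of(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index (N, 3) of world points; may fall outside the grid."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return np.rint(
            (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)
        ).astype(np.intp)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)

    def meshgrid_points(self, dtype=np.float32) -> np.ndarray:
        """All voxel centers as an (nx, ny, nz, 3) array (cached)."""
        cache = _MESH_CACHE
        key = (self.shape, self.spacing_mm, self.origin_mm, np.dtype(dtype).name)
        if key not in cache:
            xs, ys, zs = self.world_coords(dtype=dtype)
            cache[key] = np.stack(
                np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1
            ).astype(dtype)
        return cache[key]


_MESH_CACHE: dict = {}


@dataclass
class Mask:
    """A named binary volume living on a :class:`VoxelGrid`."""

    label: str
    voxels: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask {self.label!r} shape {self.voxels.shape} != grid {self.grid.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_volume_mm3 / 1000.0

    def indices(self) -> np.ndarray:
        """Voxel index triples (N, 3) of set voxels, in C order."""
        return np.argwhere(self.voxels)

    def centers_mm(self) -> np.ndarray:
        return self.grid.voxel_centers(self.indices())

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.label, self.voxels & other.voxels, self.grid)

    def __or__(self, other: "Mask") -> "Mask":
        return Mask(self.label, self.voxels | other.voxels, self.grid)


def dilate_mask(m: Mask, radius_mm: float) -> Mask:
    """Dilate a mask by a Euclidean ball of ``radius_mm`` in world units.

    A voxel is set in the output iff some input voxel center lies within
    ``radius_mm`` (inclusive) of its center, so anisotropic spacing is
    handled correctly.  ``radius_mm = 0`` returns an identical copy.
    """
    if radius_mm < 0:
        raise ValueError(f"dilation radius must be >= 0, got {radius_mm}")
    if radius_mm == 0 or not m.voxels.any():
        return Mask(m.label, m.voxels.copy(), m.grid)
    dist = ndimage.distance_transform_edt(~m.voxels, sampling=m.grid.spacing_mm)
    return Mask(m.label, dist <= radius_mm, m.grid)


def erode_mask(m: Mask, radius_mm: float) -> Mask:
    """Erode by a Euclidean ball in world units (complement of dilation)."""
    if radius_mm < 0:
        raise ValueError(f"erosion radius must be >= 0, got {radius_mm}")
    if radius_mm == 0:
        return Mask(m.label, m.voxels.copy(), m.grid)
    dist = ndimage.distance_transform_edt(m.voxels, sampling=m.grid.spacing_mm)
    return Mask(m.label, dist > radius_mm, m.grid)


def surface_distance_mm(a: Mask, b: Mask) -> float:
    """Minimum center-to-center distance between two masks (0 if overlapping)."""
    if not a.voxels.any() or not b.voxels.any():
        return float("inf")
    if (a.voxels & b.voxels).any():
        return 0.0
    dist = ndimage.distance_transform_edt(~a.voxels, sampling=a.grid.spacing_mm)
    return float(dist[b.voxels].min())


def ray_grid_voxels(
    grid: VoxelGrid,
    source_mm: np.ndarray,
    direction: np.ndarray,
    t_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (Siddon-style) voxel traversal of a ray through a grid.

    The ray is ``source + t * direction`` with ``direction`` a unit vector
    and ``t`` in mm.  Voxels are treated as axis-aligned boxes centered on
    the lattice points.  Returns ``(indices, t_edges)`` where ``indices``
    is (N, 3) in traversal order and ``t_edges`` is (N + 1,): voxel ``i``
    occupies ``t_edges[i] .. t_edges[i + 1]`` along the ray.
    """
    src = np.asarray(source_mm, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be nonzero")
    d = d / norm
    o = np.asarray(grid.origin_mm)
    sp = np.asarray(grid.spacing_mm)
    lo = o - sp / 2.0
    hi = o + (np.asarray(grid.shape) - 0.5) * sp

    # clip the ray to the grid bounding box
    t0, t1 = 0.0, np.inf if t_max is None else float(t_max)
    for ax in range(3):
        if d[ax] == 0.0:
            if not (lo[ax] <= src[ax] <= hi[ax]):
                return np.empty((0, 3), dtype=np.intp), np.empty(1)
        else:
            ta = (lo[ax] - src[ax]) / d[ax]
            tb = (hi[ax] - src[ax]) / d[ax]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if not (t1 > t0):
        return np.empty((0, 3), dtype=np.intp), np.empty(1)

    # all boundary-plane crossings inside [t0, t1]
    ts = [np.array([t0, t1])]
    for ax in range(3):
        if d[ax] != 0.0:
            planes = lo[ax] + sp[ax] * np.arange(1, grid.shape[ax])
            tk = (planes - src[ax]) / d[ax]
            ts.append(tk[(tk > t0) & (tk < t1)])
    t_edges = np.unique(np.concatenate(ts))
    if len(t_edges) < 2:
        return np.empty((0, 3), dtype=np.intp), np.empty(1)
    t_mid = 0.5 * (t_edges[:-1] + t_edges[1:])
    pts = src[None, :] + t_mid[:, None] * d[None, :]
    idx = np.rint((pts - o) / sp).astype(np.intp)
    keep = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    # boundary-clipped rays can produce degenerate end segments; drop them
    if not keep.all():
        first = np.argmax(keep)
        last = len(keep) - np.argmax(keep[::-1])
        idx = idx[first:last]
        t_edges = t_edges[first : last + 1]
    return idx, t_edges


def first_entry_depth(
    grid: VoxelGrid,
    mask_voxels: np.ndarray,
    source_mm: np.ndarray,
    direction: np.ndarray,
    t_max: float | None = None,
) -> float | None:
    """Depth (mm from source) at which a ray first enters a binary volume.

    Returns ``None`` when the ray never intersects the volume.
    """
    idx, t_edges = ray_grid_voxels(grid, source_mm, direction, t_max=t_max)
    if len(idx) == 0:
        return None
    inside = mask_voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
    hits = np.flatnonzero(inside)
    if len(hits) == 0:
        return None
    return float(t_edges[hits[0]])
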