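"""Analytic beam dose deposition and ray-structure geometry.

A beam is a divergent cone from a source node toward a target point.
The per-MU dose at a point combines inverse-square falloff from the
source, exponential attenuation with water-equivalent depth past the
body entry, and a flat-core/Gaussian-penumbra off-axis profile evaluated
at the point's own distance from the source (divergent geometry):

    dose(p) = k0 * (SAD / dist)^2 * exp(-mu * depth) * profile(r, s)

The model is deliberately simple — homogeneous water body, no build-up
region, no scatter — but is exactly linear in MU and superposes across
beams, which is what the sequencing and dose-rate analyses rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import Mask, VoxelGrid, first_entry_depth, ray_grid_voxels

__all__ = [
    "SAD_MM",
    "COLLIMATORS_MM",
    "Node",
    "Beam",
    "DoseGrid",
    "make_nodes",
    "node_sector",
    "beam_dose_per_mu",
    "dose_per_mu_at_points",
    "body_entry_depth",
    "ray_structure_entries",
    "plan_dose",
]

SAD_MM = 800.0  # source-axis distance: node hemisphere radius
MU_ATT = 0.004  # effective attenuation, 1/mm
PENUMBRA_SIGMA_MM = 2.5
CORE_FRACTION = 0.8  # flat profile out to this fraction of the field radius
CAL_DEPTH_MM = 15.0
# 1 MU deposits 1 cGy on axis at 15 mm depth with the source at SAD
K0_GY_PER_MU = 0.01 * np.exp(MU_ATT * CAL_DEPTH_MM)

COLLIMATORS_MM = (20.0, 25.0, 30.0, 35.0)
SECTORS = ("anterior", "left_lateral", "right_lateral")


@dataclass(frozen=True)
class Node:
    """A robot source position on the hemisphere around the target."""

    id: int
    position_mm: tuple[float, float, float]
    sector: str

    @property
    def position(self) -> np.ndarray:
        return np.asarray(self.position_mm)


@dataclass
class Beam:
    """One beam: source node, aim point, collimator, and MU weight."""

    node: Node
    target_point_mm: np.ndarray
    collimator_diameter_mm: float = 25.0
    mu: float = 0.0
    id: int = -1
    target_label: str = ""  # which PTV the beam was aimed at (planning metadata)

    def __post_init__(self) -> None:
        self.target_point_mm = np.asarray(self.target_point_mm, dtype=float)
        if not np.isfinite(self.mu) or self.mu < 0:
            raise ValueError(f"mu must be finite and >= 0, got {self.mu}")

    @property
    def source(self) -> np.ndarray:
        return self.node.position

    @property
    def direction(self) -> np.ndarray:
        d = self.target_point_mm - self.source
        return d / np.linalg.norm(d)


@dataclass
class DoseGrid:
    """Dose values in Gy on a voxel grid."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("dose shape does not match grid")

    def __add__(self, other: "DoseGrid") -> "DoseGrid":
        return DoseGrid(self.values + other.values, self.grid)

    def __mul__(self, k: float) -> "DoseGrid":
        return DoseGrid(self.values * k, self.grid)

    __rmul__ = __mul__

    def dmax(self, mask: Mask | None = None) -> float:
        v = self.values[mask.voxels] if mask is not None else self.values
        return float(v.max()) if v.size else 0.0


def node_sector(position_mm, centroid_mm) -> str:
    """Sector from the azimuth of the node in the axial plane.

    Azimuth 0 is straight anterior of the centroid; |azimuth| <= 30 deg
    is ``anterior``, beyond that patient-left azimuths are
    ``left_lateral`` and patient-right ``right_lateral``.
    """
    rel = np.asarray(position_mm, dtype=float) - np.asarray(centroid_mm, dtype=float)
    az = np.degrees(np.arctan2(rel[0], -rel[1]))
    if abs(az) <= 30.0:
        return "anterior"
    return "left_lateral" if az > 0 else "right_lateral"


def make_nodes(
    n: int = 100,
    centroid_mm=(0.0, 0.0, 0.0),
    sad_mm: float = SAD_MM,
) -> list[Node]:
    """Quasi-uniform nodes on the anterior source hemisphere.

    Deterministic Fibonacci-lattice points of radius ``sad_mm`` around
    the target centroid, restricted to the half-space anterior of the
    couch (no beams through the table).
    """
    c = np.asarray(centroid_mm, dtype=float)
    golden = (1 + 5**0.5) / 2
    pts = []
    m = 4 * n  # oversample the sphere, keep the anterior half
    for k in range(m):
        z = 1 - 2 * (k + 0.5) / m
        r = np.sqrt(max(0.0, 1 - z * z))
        phi = 2 * np.pi * k / golden
        pts.append((r * np.cos(phi), r * np.sin(phi), z))
    pts = np.asarray(pts)
    anterior = pts[pts[:, 1] < -0.05]
    # thin deterministically to n, spread over the hemisphere
    step = max(1, len(anterior) // n)
    chosen = anterior[::step][:n]
    nodes = []
    for i, u in enumerate(chosen):
        pos = c + sad_mm * u
        nodes.append(Node(id=i, position_mm=tuple(pos), sector=node_sector(pos, c)))
    return nodes


def body_entry_depth(beam: Beam, body: Mask) -> float | None:
    """Depth (mm from source) where the central axis enters the body."""
    return first_entry_depth(body.grid, body.voxels, beam.source, beam.direction)


def dose_per_mu_at_points(
    beam: Beam, points_mm: np.ndarray, entry_depth_mm: float
) -> np.ndarray:
    """Per-MU dose (Gy) of one beam at arbitrary world points."""
    pts = np.asarray(points_mm)
    src = beam.source.astype(pts.dtype if pts.dtype.kind == "f" else np.float64)
    d = beam.direction.astype(src.dtype)
    rel = pts - src
    s = rel @ d
    dist2 = np.einsum("...i,...i->...", rel, rel)
    r = np.sqrt(np.maximum(dist2 - s * s, 0.0))
    field_r = (beam.collimator_diameter_mm / 2.0) * np.maximum(s, 1e-6) / SAD_MM
    core = CORE_FRACTION * field_r
    excess = np.maximum(r - core, 0.0)
    prof = np.exp(-(excess * excess) / (2.0 * PENUMBRA_SIGMA_MM**2))
    depth = s - entry_depth_mm
    dose = (
        K0_GY_PER_MU
        * (SAD_MM**2 / np.maximum(dist2, 1.0))
        * np.exp(-MU_ATT * np.maximum(depth, 0.0))
        * prof
    )
    dose[depth < 0] = 0.0
    return dose


def beam_dose_per_mu(beam: Beam, grid: VoxelGrid, body: Mask) -> DoseGrid:
    """Per-MU dose of one beam on the whole grid (zero before body entry)."""
    entry = body_entry_depth(beam, body)
    if entry is None:
        warnings.warn(
            f"beam from node {beam.node.id} misses the body; zero dose",
            stacklevel=2,
        )
        return DoseGrid(np.zeros(grid.shape), grid)
    pts = grid.meshgrid_points()
    vals = dose_per_mu_at_points(beam, pts, entry).astype(np.float64)
    return DoseGrid(vals, grid)


def plan_dose(beams: list[Beam], grid: VoxelGrid, body: Mask) -> DoseGrid:
    """Total dose of a weighted beam list (sum of per-beam grids)."""
    total = np.zeros(grid.shape)
    pts = grid.meshgrid_points()
    for b in beams:
        if b.mu == 0:
            continue
        entry = body_entry_depth(b, body)
        if entry is None:
            continue
        total += b.mu * dose_per_mu_at_points(b, pts, entry)
    return DoseGrid(total, grid)


def ray_structure_entries(
    beam: Beam, structures, labels: list[str] | None = None
) -> list[tuple[str, float]]:
    """Ordered (label, entry depth mm) of structures hit by the central axis.

    Uses exact voxel traversal; a structure appears iff the axis passes
    through at least one of its voxels, at the depth where it first does.
    """
    masks = structures.as_dict() if hasattr(structures, "as_dict") else dict(structures)
    if labels is not None:
        masks = {k: masks[k] for k in labels if k in masks}
    if not masks:
        return []
    grid = next(iter(masks.values())).grid
    idx, t_edges = ray_grid_voxels(grid, beam.source, beam.direction)
    if len(idx) == 0:
        return []
    entries = []
    for label, m in masks.items():
        inside = m.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
        hits = np.flatnonzero(inside)
        if len(hits):
            entries.append((label, float(t_edges[hits[0]])))
    entries.sort(key=lambda e: e[1])
    return entries
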