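"""Seeded synthetic cardiac phantoms for AF radiosurgery planning studies.

The phantom emulates the planning geometry of pulmonary-vein isolation:
a left atrium (LA) with four pulmonary veins (PVs), ring-shaped ablation
lesions 4-6 mm wide and 2-4 mm deep encircling each PV ostium at the
antrum, planning target volumes (PTVs) obtained by isotropic 3 mm
expansion, and the organs at risk that dominate plan feasibility — the
esophagus (placed according to the five clinically observed location
classes), the bronchial tree, and the left coronary artery.

Everything is generated deterministically from a seed; no external data
is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Mask, VoxelGrid, dilate_mask, surface_distance_mm

__all__ = [
    "ESOPHAGUS_CLASSES",
    "ESOPHAGUS_CLASS_WEIGHTS",
    "PhantomSpec",
    "StructureSet",
    "generate_phantom",
    "sample_esophagus_class",
    "dilate_mask",
]

#: Esophagus location classes along the posterior LA wall and their
#: observed population frequencies (fraction of patients).
ESOPHAGUS_CLASSES = (
    "post-RIPV",
    "central-near-right",
    "central-away",
    "central-near-left",
    "post-LIPV",
)
ESOPHAGUS_CLASS_WEIGHTS = (0.105, 0.090, 0.196, 0.196, 0.413)


@dataclass
class PhantomSpec:
    """Configuration of the synthetic phantom.

    Lesion width (along the vein) is drawn uniformly from
    ``lesion_width_mm`` and transmural depth from ``lesion_depth_mm``;
    both intervals reflect the target contours used clinically.  LA and
    PV dimensions are population-typical defaults, not patient data.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    la_semi_axes_mm: tuple[float, float, float] = (25.0, 19.0, 23.0)
    la_center_mm: tuple[float, float, float] = (0.0, 10.0, 0.0)
    pv_radius_mm: float = 8.5
    pv_length_mm: float = 32.0
    lesion_width_mm: tuple[float, float] = (4.0, 6.0)
    lesion_depth_mm: tuple[float, float] = (2.0, 4.0)
    margin_mm: float = 3.0
    esophagus_class: str = "sample"
    class_weights: tuple[float, ...] = ESOPHAGUS_CLASS_WEIGHTS
    esophagus_radius_mm: float = 7.0
    pv_variant: str = "typical"  # "typical" | "common_left_trunk" | "right_middle"
    with_probe: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("esophagus class weights must sum to 1")
        if self.esophagus_class != "sample" and self.esophagus_class not in ESOPHAGUS_CLASSES:
            raise ValueError(
                f"esophagus_class must be 'sample' or one of {ESOPHAGUS_CLASSES}"
            )
        if self.pv_variant not in ("typical", "common_left_trunk", "right_middle"):
            raise ValueError(f"unknown pv_variant {self.pv_variant!r}")


@dataclass
class StructureSet:
    """All phantom structures on a shared grid plus the septal tracking point."""

    lesion_R: Mask
    lesion_L: Mask
    RPTV: Mask
    LPTV: Mask
    esophagus: Mask
    bronchial_tree: Mask
    LCA: Mask
    heart: Mask
    lungs: Mask
    body: Mask
    septum_point_mm: np.ndarray
    probe: Optional[Mask] = None
    esophagus_class: str = ""
    pv_axes: dict = field(default_factory=dict)  # name -> (ostium_mm, unit direction)

    def oars(self) -> dict[str, Mask]:
        return {
            "esophagus": self.esophagus,
            "bronchial_tree": self.bronchial_tree,
            "LCA": self.LCA,
            "heart": self.heart,
            "lungs": self.lungs,
        }

    def ptvs(self) -> dict[str, Mask]:
        return {"RPTV": self.RPTV, "LPTV": self.LPTV}

    @property
    def ptv_combined(self) -> Mask:
        return Mask("PTV", self.RPTV.voxels | self.LPTV.voxels, self.RPTV.grid)

    def as_dict(self) -> dict[str, Mask]:
        d = {
            "lesion_R": self.lesion_R,
            "lesion_L": self.lesion_L,
            "RPTV": self.RPTV,
            "LPTV": self.LPTV,
            **self.oars(),
            "body": self.body,
        }
        if self.probe is not None:
            d["probe"] = self.probe
        return d


def sample_esophagus_class(
    rng: np.random.Generator, weights: tuple[float, ...] = ESOPHAGUS_CLASS_WEIGHTS
) -> str:
    """Draw one esophagus location class from the population frequencies."""
    return ESOPHAGUS_CLASSES[int(rng.choice(len(ESOPHAGUS_CLASSES), p=weights))]


# ---------------------------------------------------------------------------
# geometric primitives (evaluated on the voxel-center lattice)


def _ellipsoid(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    pts = grid.meshgrid_points()
    q = (pts - np.asarray(center, dtype=np.float32)) / np.asarray(
        semi_axes, dtype=np.float32
    )
    return np.einsum("...i,...i->...", q, q) <= 1.0


def _elliptic_cylinder_z(grid: VoxelGrid, center_xy, semi_xy) -> np.ndarray:
    pts = grid.meshgrid_points()
    qx = (pts[..., 0] - center_xy[0]) / semi_xy[0]
    qy = (pts[..., 1] - center_xy[1]) / semi_xy[1]
    return qx * qx + qy * qy <= 1.0


def _capsule(grid: VoxelGrid, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1."""
    pts = grid.meshgrid_points()
    p0 = np.asarray(p0, dtype=np.float32)
    d = np.asarray(p1, dtype=np.float32) - p0
    L2 = float(d @ d)
    rel = pts - p0
    t = np.clip(np.einsum("...i,i->...", rel, d) / L2, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    r2 = np.einsum("...i,...i->...", pts - closest, pts - closest)
    return r2 <= radius * radius


def _ring_shell(grid: VoxelGrid, ostium, direction, r_in, r_out, width) -> np.ndarray:
    """Annular shell around a PV axis: axial span [0, width] from the
    ostium, radial span (r_in, r_out]."""
    pts = grid.meshgrid_points()
    o = np.asarray(ostium, dtype=np.float32)
    d = np.asarray(direction, dtype=np.float32)
    d = d / np.linalg.norm(d)
    rel = pts - o
    s = np.einsum("...i,i->...", rel, d)
    r2 = np.einsum("...i,...i->...", rel, rel) - s * s
    return (s >= 0) & (s <= width) & (r2 > r_in * r_in) & (r2 <= r_out * r_out)


def _box(grid: VoxelGrid, lo, hi) -> np.ndarray:
    pts = grid.meshgrid_points()
    lo = np.asarray(lo, dtype=np.float32)
    hi = np.asarray(hi, dtype=np.float32)
    return np.all((pts >= lo) & (pts <= hi), axis=-1)


def _pv_directions(variant: str) -> dict[str, np.ndarray]:
    """Unit directions of the PV axes leaving the LA (patient frame)."""

    def u(v):
        v = np.asarray(v, dtype=float)
        return v / np.linalg.norm(v)

    dirs = {
        "RSPV": u((-0.80, 0.25, 0.55)),
        "RIPV": u((-0.80, 0.40, -0.45)),
        "LSPV": u((0.80, 0.25, 0.55)),
        "LIPV": u((0.80, 0.40, -0.45)),
    }
    if variant == "common_left_trunk":
        dirs.pop("LSPV")
        dirs.pop("LIPV")
        dirs["LCPV"] = u((0.85, 0.35, 0.05))
    elif variant == "right_middle":
        dirs["RMPV"] = u((-0.85, 0.35, 0.05))
    return dirs


def _ellipsoid_surface_point(center, semi_axes, direction) -> np.ndarray:
    """Point where a ray from the ellipsoid center exits the surface."""
    d = np.asarray(direction, dtype=float)
    t = 1.0 / np.sqrt(np.sum((d / np.asarray(semi_axes)) ** 2))
    return np.asarray(center, dtype=float) + t * d


def _place_esophagus(
    grid: VoxelGrid,
    cls: str,
    rptv: Mask,
    lptv: Mask,
    pv_axes: dict,
    radius: float,
) -> Mask:
    """Place the esophageal tube (vertical, full z extent) per location class.

    Near classes put the tube within 3 mm of the relevant PTV surface,
    "central-away" more than 10 mm from both; positions are solved
    against the realized PTV masks so the invariants hold on any grid.
    """
    right_x = np.mean([o[0] for n, (o, _) in pv_axes.items() if n.startswith("R")])
    left_x = np.mean([o[0] for n, (o, _) in pv_axes.items() if n.startswith("L")])
    # near classes: the tube abuts the PTV (clinically: in contact with
    # the target region), still without overlapping it
    if cls == "post-RIPV":
        x0, target, gap = right_x, rptv, 0.3
    elif cls == "central-near-right":
        x0, target, gap = right_x / 2.0, rptv, 0.3
    elif cls == "central-near-left":
        x0, target, gap = left_x / 2.0, lptv, 0.3
    elif cls == "post-LIPV":
        x0, target, gap = left_x, lptv, 0.3
    elif cls == "central-away":
        x0 = (right_x + left_x) / 2.0
        target = Mask("PTV", rptv.voxels | lptv.voxels, grid)
        gap = 12.0
    else:  # pragma: no cover - validated upstream
        raise ValueError(cls)

    # solve tube y so that the min axis distance to the target equals radius+gap
    tv = target.centers_mm()
    dxy2 = (tv[:, 0] - x0) ** 2
    y_post = float(tv[:, 1].max())
    y0 = y_post + radius + gap
    for _ in range(40):
        dist = float(np.sqrt(dxy2 + (tv[:, 1] - y0) ** 2).min()) - radius
        if abs(dist - gap) < 0.25:
            break
        y0 += gap - dist
    tube = Mask("esophagus", _elliptic_cylinder_z(grid, (x0, y0), (radius, radius)), grid)

    if cls != "central-away":
        # verify on the realized masks; nudge if discretization broke the band
        for _ in range(10):
            d = surface_distance_mm(tube, target)
            if 0.0 < d <= 3.0:
                break
            y0 += -0.5 if d > 3.0 else 0.5
            tube = Mask(
                "esophagus", _elliptic_cylinder_z(grid, (x0, y0), (radius, radius)), grid
            )
    return tube


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, StructureSet]:
    """Build the synthetic anatomy and structure set from a spec.

    Deterministic for a fixed spec and seed.  Raises ``ValueError`` when
    the grid is too coarse to represent the sampled lesion depth.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing_mm)
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing))
    grid = VoxelGrid(shape, spacing, origin)

    width = float(rng.uniform(*spec.lesion_width_mm))
    depth = float(rng.uniform(*spec.lesion_depth_mm))
    if max(spacing) > depth:
        raise ValueError(
            f"grid spacing {max(spacing)} mm too coarse for a {depth:.1f} mm "
            "lesion depth; refine the grid or increase lesion_depth_mm"
        )
    cls = spec.esophagus_class
    if cls == "sample":
        cls = sample_esophagus_class(rng, spec.class_weights)

    la_c = np.asarray(spec.la_center_mm)
    la_ax = np.asarray(spec.la_semi_axes_mm)

    body_semi = (
        min(110.0, grid.extent_mm[0] / 2 - 8),
        min(90.0, grid.extent_mm[1] / 2 - 8),
    )
    body = Mask("body", _elliptic_cylinder_z(grid, (0.0, 0.0), body_semi), grid)
    heart = Mask("heart", _ellipsoid(grid, (0.0, 8.0, -6.0), (58.0, 48.0, 58.0)), grid)
    heart = heart & body

    la = _ellipsoid(grid, la_c, la_ax)
    pv_dirs = _pv_directions(spec.pv_variant)
    pv_axes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pv_vox = np.zeros(shape, dtype=bool)
    for name, d in pv_dirs.items():
        ostium = _ellipsoid_surface_point(la_c, la_ax, d)
        pv_axes[name] = (ostium, d)
        r = spec.pv_radius_mm * (1.35 if name == "LCPV" else 1.0)
        pv_vox |= _capsule(grid, ostium, ostium + d * spec.pv_length_mm, r)

    # one wide antral ring per PV pair (circumferential isolation pattern):
    # a tube shell of the sampled transmural depth, extending the sampled
    # width along the mean vein direction from the antrum plane, and wide
    # enough to encircle every ostium of the pair
    def pair_ring(names: list[str]) -> np.ndarray:
        ostia = np.array([pv_axes[n][0] for n in names])
        dirs = np.array([pv_axes[n][1] for n in names])
        d = dirs.mean(axis=0)
        d = d / np.linalg.norm(d)
        o = ostia.mean(axis=0)
        radial = ostia - o - ((ostia - o) @ d)[:, None] * d
        radii = np.array(
            [spec.pv_radius_mm * (1.35 if n == "LCPV" else 1.0) for n in names]
        )
        r_in = float((np.linalg.norm(radial, axis=1) + radii).max()) + 0.5
        return _ring_shell(grid, o, d, r_in, r_in + depth, width)

    rights = [n for n in pv_axes if n.startswith("R")]
    lefts = [n for n in pv_axes if n.startswith("L")]
    lesion_R = Mask("lesion_R", pair_ring(rights) & heart.voxels, grid)
    lesion_L = Mask("lesion_L", pair_ring(lefts) & heart.voxels, grid)

    rptv = dilate_mask(lesion_R, spec.margin_mm)
    rptv.label = "RPTV"
    lptv = dilate_mask(lesion_L, spec.margin_mm)
    lptv.label = "LPTV"
    rptv = rptv & body
    lptv = lptv & body

    esophagus = _place_esophagus(
        grid, cls, rptv, lptv, pv_axes, spec.esophagus_radius_mm
    )
    esophagus = esophagus & body
    esophagus.label = "esophagus"

    # bronchial tree: trachea + main bronchi, anterior-superior of the LA,
    # close to the right antrum but clear of the PTVs in this favorable
    # default anatomy
    carina = np.array([-4.0, -26.0, 44.0])
    bron = _capsule(grid, carina, carina + np.array([0.0, -2.0, 80.0]), 8.0)
    bron |= _capsule(grid, carina, np.array([-50.0, -14.0, 16.0]), 6.5)
    bron |= _capsule(grid, carina, np.array([44.0, -14.0, 18.0]), 6.5)
    bronchial = Mask("bronchial_tree", bron & body.voxels, grid)

    lca = _capsule(grid, np.array([4.0, -22.0, 4.0]), np.array([40.0, -12.0, -34.0]), 3.0)
    lca_m = Mask("LCA", lca & body.voxels, grid)

    lungs = _ellipsoid(grid, (-68.0, 8.0, 5.0), (36.0, 58.0, 92.0))
    lungs |= _ellipsoid(grid, (68.0, 8.0, 5.0), (36.0, 58.0, 92.0))
    lungs &= ~heart.voxels & ~bron & body.voxels
    lungs_m = Mask("lungs", lungs, grid)

    # heart encloses LA, PV roots and lesions by construction; enforce anyway
    heart.voxels |= la | lesion_R.voxels | lesion_L.voxels
    heart = heart & body

    probe = None
    if spec.with_probe:
        y_skin = -body_semi[1] * np.sqrt(max(0.0, 1.0 - (5.0 / body_semi[0]) ** 2))
        probe = Mask(
            "probe",
            _box(
                grid,
                (-35.0, y_skin - 8.0, -7.5),
                (25.0, y_skin + 7.0, 7.5),
            ),
            grid,
        )

    septum = la_c + np.array([-(la_ax[0] + 3.0), 0.0, 0.0])

    structures = StructureSet(
        lesion_R=lesion_R,
        lesion_L=lesion_L,
        RPTV=rptv,
        LPTV=lptv,
        esophagus=esophagus,
        bronchial_tree=bronchial,
        LCA=lca_m,
        heart=heart,
        lungs=lungs_m,
        body=body,
        septum_point_mm=septum,
        probe=probe,
        esophagus_class=cls,
        pv_axes=pv_axes,
    )
    return grid, structures
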