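"""Respiratory/cardiac displacement fields and surrogate-tracked 4D dose.

The tracking surrogate is a catheter tip at the right atrial septum.
Beams follow the surrogate exactly, but the target (especially the left
pulmonary veins) moves less than the septum — the *differential* motion
that degrades coverage.  With a homogeneous water-equivalent body, a
rigid surrogate shift translates the whole dose cloud with it, so the
phase dose is the static distribution translated by the surrogate
displacement and the accumulated dose in the reference frame is

    D_acc(x) = sum_p w_p * D_static(x + u_p(x) - u_p(x_track))

where ``u_p`` is the phase displacement field defined on the reference
grid.  This forward-field pull-back makes the zero-motion and
perfect-tracking identities exact at grid points; a Jacobian fold check
still flags voxels where the field is not invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dose_engine import Beam, DoseGrid, body_entry_depth, dose_per_mu_at_points, plan_dose
from .geometry import VoxelGrid
from .phantom import StructureSet
from .planner import ConstraintSet, Plan, Prescription, coverage_at, optimize_mu

__all__ = [
    "MotionSpec",
    "DisplacementField",
    "make_fields",
    "displacement_at",
    "accumulate_4d",
    "coverage_reduction",
    "optimize_4d",
]


@dataclass
class MotionSpec:
    """Amplitudes and phase structure of the motion model.

    Septum amplitudes are the population-median respiratory excursions
    of the atrial septum per axis (inferior/superior, anterior/
    posterior, left/right, in mm).  ``differential_scale_left_pv``
    scales the motion of the left-PV region relative to the septum;
    respiratory phase weights default to an expiration-dominant 0.6/0.4
    split (end-expiration is the reference phase).
    """

    septum_is_mm: float = 12.8
    septum_ap_mm: float = 13.3
    septum_lr_mm: float = 4.1
    differential_scale_left_pv: float = 0.6
    cardiac_amplitude_mm: float = 10.0
    n_cardiac_phases: int = 8
    resp_phase_weights: tuple[float, float] = (0.6, 0.4)
    cardiac_falloff_mm: float = 25.0

    def __post_init__(self) -> None:
        for a in (self.septum_is_mm, self.septum_ap_mm, self.septum_lr_mm,
                  self.cardiac_amplitude_mm):
            if a < 0:
                raise ValueError("amplitudes must be >= 0")
        if not (0.0 <= self.differential_scale_left_pv <= 1.0):
            raise ValueError("differential scale must be in [0, 1]")

    @property
    def septum_vector_mm(self) -> np.ndarray:
        """Inspiration displacement of the septum in the (x, y, z) frame:
        toward patient-left, anterior, and inferior."""
        return np.array([self.septum_lr_mm, -self.septum_ap_mm, -self.septum_is_mm])


@dataclass
class DisplacementField:
    """One motion phase: weight and a vector field (mm) on the reference grid."""

    phase_id: int
    weight: float
    field: np.ndarray  # (nx, ny, nz, 3) float32
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("phase weight must be in [0, 1]")
        if self.field.shape != (*self.grid.shape, 3):
            raise ValueError("field shape does not match grid")


def _validate_weights(weights: Sequence[float]) -> None:
    if abs(float(np.sum(weights)) - 1.0) > 1e-9:
        raise ValueError(f"phase weights must sum to 1, got {np.sum(weights)}")


def _differential_profile(
    grid: VoxelGrid, structures: StructureSet, factor: float
) -> np.ndarray:
    """Smooth scalar profile: 1 at the septum, ``factor`` at the left PVs.

    Smoothstep in the patient-left coordinate between the septum and the
    left-PV ostia, clamped outside.
    """
    x_sep = float(structures.septum_point_mm[0])
    left_x = [o[0] for n, (o, _) in structures.pv_axes.items() if n.startswith("L")]
    x_lpv = float(np.mean(left_x)) if left_x else x_sep + 40.0
    pts = grid.meshgrid_points()
    t = np.clip((pts[..., 0] - x_sep) / max(x_lpv - x_sep, 1e-6), 0.0, 1.0)
    smooth = t * t * (3.0 - 2.0 * t)
    return 1.0 - (1.0 - factor) * smooth


def make_fields(
    spec: MotionSpec,
    mode: str,
    structures: StructureSet,
    weights: Sequence[float] | None = None,
) -> list[DisplacementField]:
    """Build the per-phase displacement fields for one motion mode.

    ``respiratory``: two phases — end-expiration (reference, zero field)
    and end-inspiration displaced by the septum amplitudes, scaled down
    smoothly toward the left PVs by the differential factor.

    ``cardiac``: ``n_cardiac_phases`` phases of sinusoidal displacement
    along the septum-to-LA axis, amplitude peaking at the septum and
    decaying with distance (so motion at the PV antra stays small).
    """
    grid = structures.body.grid
    if mode == "respiratory":
        w = tuple(spec.resp_phase_weights) if weights is None else tuple(weights)
        _validate_weights(w)
        if len(w) != 2:
            raise ValueError("respiratory mode uses exactly 2 phases")
        zero = np.zeros((*grid.shape, 3), dtype=np.float32)
        profile = _differential_profile(
            grid, structures, spec.differential_scale_left_pv
        ).astype(np.float32)
        insp = profile[..., None] * spec.septum_vector_mm.astype(np.float32)
        return [
            DisplacementField(0, w[0], zero, grid),
            DisplacementField(1, w[1], insp, grid),
        ]
    if mode == "cardiac":
        n = spec.n_cardiac_phases
        w = tuple(np.full(n, 1.0 / n)) if weights is None else tuple(weights)
        _validate_weights(w)
        pts = grid.meshgrid_points()
        sep = structures.septum_point_mm.astype(np.float32)
        la_c = np.mean(
            [o for o, _ in structures.pv_axes.values()], axis=0
        ).astype(np.float32)
        d = la_c - sep
        d = d / max(np.linalg.norm(d), 1e-6)
        r2 = np.einsum("...i,...i->...", pts - sep, pts - sep)
        envelope = spec.cardiac_amplitude_mm * np.exp(
            -r2 / (2.0 * spec.cardiac_falloff_mm**2)
        )
        fields = []
        for k in range(n):
            g = np.sin(2.0 * np.pi * k / n)
            fields.append(
                DisplacementField(
                    k,
                    w[k],
                    (g * envelope[..., None] * d).astype(np.float32),
                    grid,
                )
            )
        return fields
    raise ValueError(f"mode must be 'respiratory' or 'cardiac', got {mode!r}")


def displacement_at(f: DisplacementField, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of the field at world points (N, 3) -> (N, 3) mm."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    coords = (pts - np.asarray(f.grid.origin_mm)) / np.asarray(f.grid.spacing_mm)
    out = np.empty_like(pts)
    for ax in range(3):
        out[:, ax] = ndimage.map_coordinates(
            f.field[..., ax].astype(np.float64), coords.T, order=1, mode="nearest"
        )
    return out


def _fold_report(fields: list[DisplacementField]) -> dict:
    """Count voxels where det(I + grad u) <= 0 (non-invertible mapping)."""
    report = {}
    for f in fields:
        sp = f.grid.spacing_mm
        J = np.zeros((*f.grid.shape, 3, 3), dtype=np.float32)
        for i in range(3):
            g = np.gradient(f.field[..., i], *sp)
            for j in range(3):
                J[..., i, j] = g[j]
            J[..., i, i] += 1.0
        det = np.linalg.det(J)
        report[f.phase_id] = int(np.count_nonzero(det <= 0))
    return report


def accumulate_4d(
    plan: Plan,
    fields: list[DisplacementField],
    structures: StructureSet,
    tracked_point_mm: np.ndarray | None,
    check_invertibility: bool = True,
) -> tuple[DoseGrid, dict]:
    """Surrogate-tracked phase-weighted dose accumulation on the reference grid.

    With ``tracked_point_mm=None`` the beams do not follow the motion at
    all (the untracked case — appropriate for cardiac phases, which the
    respiratory tracking loop does not compensate).  Returns the
    accumulated dose and a report with the per-phase surrogate shifts
    and (optionally) counts of folded voxels where the field is not
    invertible.
    """
    _validate_weights([f.weight for f in fields])
    grid = structures.body.grid
    tracked = None
    if tracked_point_mm is not None:
        tracked = np.asarray(tracked_point_mm, dtype=float)
        idx = grid.index_of(tracked)[0]
        if not grid.contains_index(idx)[0]:
            raise ValueError("tracked point lies outside the grid")
    static = plan.dose
    if static is None:
        static = plan_dose(plan.beams, grid, structures.body)
    pts = grid.meshgrid_points().astype(np.float64)
    origin = np.asarray(grid.origin_mm)
    spacing = np.asarray(grid.spacing_mm)
    acc = np.zeros(grid.shape)
    shifts = {}
    for f in fields:
        delta = (
            np.zeros(3) if tracked is None else displacement_at(f, tracked)[0]
        )
        shifts[f.phase_id] = delta.tolist()
        sample = pts + f.field.astype(np.float64) - delta
        coords = (sample - origin) / spacing
        acc += f.weight * ndimage.map_coordinates(
            static.values, [coords[..., 0], coords[..., 1], coords[..., 2]],
            order=1, mode="constant", cval=0.0,
        )
    report = {"surrogate_shift_mm": shifts}
    if check_invertibility:
        report["folded_voxels"] = _fold_report(fields)
    return DoseGrid(acc, grid), report


def coverage_reduction(
    static_dose: DoseGrid,
    accumulated_dose: DoseGrid,
    structures: StructureSet,
    rx: Prescription,
) -> dict:
    """Per-target coverage change (percentage points; losses negative)
    and organ-at-risk Dmax differences (accumulated minus static, Gy)."""
    if static_dose.grid.shape != accumulated_dose.grid.shape:
        raise ValueError("dose grids must match")
    out: dict = {}
    for label, mask in structures.ptvs().items():
        c_stat = coverage_at(static_dose, mask, rx.dose_gy)
        c_acc = coverage_at(accumulated_dose, mask, rx.dose_gy)
        out[f"{label}_coverage_reduction_pp"] = 100.0 * (c_acc - c_stat)
    out["oar_dmax_diff_gy"] = {
        o: accumulated_dose.dmax(m) - static_dose.dmax(m)
        for o, m in structures.oars().items()
        if o in ("esophagus", "bronchial_tree")
    }
    return out


def optimize_4d(
    candidates: list[Beam],
    fields: list[DisplacementField],
    structures: StructureSet,
    rx: Prescription,
    constraints: ConstraintSet,
    tracked_point_mm: np.ndarray,
    seed: int = 0,
) -> Plan:
    """MU optimization against the phase-accumulated (not static) dose.

    Per-beam doses at every sample point are evaluated at the
    motion-displaced positions of each phase and phase-weight-summed, so
    the coverage rescale pins the *accumulated* dose to the
    prescription.  With zero motion this reduces exactly to the static
    optimizer.
    """
    _validate_weights([f.weight for f in fields])
    grid = structures.body.grid
    body = structures.body
    tracked = np.asarray(tracked_point_mm, dtype=float)
    deltas = [displacement_at(f, tracked)[0] for f in fields]

    def evaluator(beams: list[Beam], points: np.ndarray) -> np.ndarray:
        if len(points) == 0:
            return np.zeros((0, len(beams)))
        A = np.zeros((len(points), len(beams)))
        disp = [displacement_at(f, points) for f in fields]
        for j, b in enumerate(beams):
            entry = body_entry_depth(b, body)
            if entry is None:
                continue
            col = np.zeros(len(points))
            for f, u, delta in zip(fields, disp, deltas):
                col += f.weight * dose_per_mu_at_points(b, points + u - delta, entry)
            A[:, j] = col
        return A

    def builder(beams: list[Beam]) -> DoseGrid:
        static = plan_dose(beams, grid, body)
        holder = Plan(beams=beams, prescription=rx, dose=static)
        acc, _ = accumulate_4d(
            holder, fields, structures, tracked, check_invertibility=False
        )
        return acc

    plan = optimize_mu(
        candidates,
        structures,
        rx,
        constraints,
        seed=seed,
        mode="4d",
        dose_evaluator=evaluator,
        dose_builder=builder,
    )
    plan.meta["static_dose"] = plan_dose(plan.beams, grid, body)
    return plan
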