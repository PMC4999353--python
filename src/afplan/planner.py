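"""Candidate-beam generation, MU optimization, probe blocking, constraints.

The optimizer is an iteratively reweighted nonnegative least-squares fit
of beam monitor units against a uniform target dose, with one-sided
penalties on organ-at-risk voxels, followed by a global rescale that
pins the coverage quantile of the PTV exactly to the prescription, MU
pruning, and one re-fit.  It reproduces the clinical workflow's outputs
(a weighted beam list meeting a coverage rule under DVH constraints)
without any claim of matching a commercial optimizer beam-for-beam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dose_engine import (
    Beam,
    DoseGrid,
    Node,
    body_entry_depth,
    dose_per_mu_at_points,
    plan_dose,
)
from .geometry import Mask, dilate_mask, ray_grid_voxels
from .phantom import StructureSet

__all__ = [
    "Prescription",
    "OARLimit",
    "ConstraintSet",
    "Plan",
    "DIVIDED_SECTORS",
    "generate_candidates",
    "optimize_mu",
    "block_probe",
    "check_constraints",
    "coverage_at",
]

#: Divided-node-set assignment: which hemisphere sectors may target each PTV.
DIVIDED_SECTORS = {
    "RPTV": ("anterior", "right_lateral"),
    "LPTV": ("left_lateral", "anterior"),
}
FULL_SECTORS = {
    "RPTV": ("anterior", "left_lateral", "right_lateral"),
    "LPTV": ("anterior", "left_lateral", "right_lateral"),
}


@dataclass
class Prescription:
    """Single-fraction prescription: dose to a minimum coverage fraction."""

    dose_gy: float = 25.0
    min_coverage: float = 0.99
    isodose_fraction: float = 0.80  # informational only

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.dose_gy <= 0:
            raise ValueError("dose_gy must be > 0")


@dataclass(frozen=True)
class OARLimit:
    """One dose limit on one organ.

    ``kind`` is ``dmax`` or ``vx`` (volume in cc receiving >= dose_gy).
    ``severity`` ``soft`` corresponds to the low-grade side-effect
    threshold (strict ``<``: equality fails); ``hard`` to the severe
    threshold treated as a planning limit (``<=``: equality passes).
    """

    organ: str
    kind: str
    limit: float
    dose_gy: float = 0.0
    severity: str = "soft"

    @property
    def name(self) -> str:
        if self.kind == "dmax":
            op = "<" if self.severity == "soft" else "<="
            return f"{self.organ} Dmax {op} {self.limit:g} Gy"
        op = "<" if self.severity == "soft" else "<="
        return f"{self.organ} V{self.dose_gy:g}Gy {op} {self.limit:g} cc"


def _default_limits() -> tuple[OARLimit, ...]:
    return (
        OARLimit("esophagus", "dmax", 14.0, severity="soft"),
        OARLimit("esophagus", "dmax", 19.0, severity="hard"),
        OARLimit("esophagus", "vx", 1.0, dose_gy=9.0, severity="soft"),
        OARLimit("esophagus", "vx", 5.0, dose_gy=14.5, severity="hard"),
        OARLimit("bronchial_tree", "dmax", 14.0, severity="soft"),
        OARLimit("bronchial_tree", "dmax", 22.0, severity="hard"),
        OARLimit("bronchial_tree", "vx", 1.0, dose_gy=10.0, severity="soft"),
        OARLimit("bronchial_tree", "vx", 4.0, dose_gy=10.5, severity="hard"),
        OARLimit("LCA", "dmax", 16.0, severity="soft"),
        OARLimit("major_vessels", "dmax", 37.0, severity="hard"),
        OARLimit("major_vessels", "vx", 10.0, dose_gy=31.0, severity="hard"),
    )


@dataclass
class ConstraintSet:
    """The DVH constraint table for close organs at risk."""

    limits: tuple[OARLimit, ...] = field(default_factory=_default_limits)

    def for_organ(self, organ: str) -> list[OARLimit]:
        return [L for L in self.limits if L.organ == organ]

    @property
    def organs(self) -> list[str]:
        seen: list[str] = []
        for L in self.limits:
            if L.organ not in seen:
                seen.append(L.organ)
        return seen


@dataclass
class Plan:
    """An ordered, MU-weighted beam list with its evaluation artifacts."""

    beams: list[Beam]
    prescription: Prescription
    seed: int = 0
    mode: str = "regular"
    dose: Optional[DoseGrid] = None
    coverage: float = float("nan")
    feasible: bool = False
    constraint_report: dict = field(default_factory=dict)
    ptv_voxel_indices: Optional[np.ndarray] = None  # (N, 3) into the grid
    ptv_dose_matrix: Optional[np.ndarray] = None  # (N voxels, n beams), Gy
    meta: dict = field(default_factory=dict)

    @property
    def total_mu(self) -> float:
        return float(sum(b.mu for b in self.beams))

    @property
    def n_beams(self) -> int:
        return len(self.beams)

    @property
    def n_nodes(self) -> int:
        return len({b.node.id for b in self.beams})

    def reordered(self, order: Sequence[int]) -> "Plan":
        """Same beams in a new delivery order (dose artifacts preserved)."""
        if sorted(order) != list(range(len(self.beams))):
            raise ValueError("order must be a permutation of the beam indices")
        p = Plan(
            beams=[self.beams[i] for i in order],
            prescription=self.prescription,
            seed=self.seed,
            mode=self.mode,
            dose=self.dose,
            coverage=self.coverage,
            feasible=self.feasible,
            constraint_report=self.constraint_report,
            ptv_voxel_indices=self.ptv_voxel_indices,
            ptv_dose_matrix=(
                None if self.ptv_dose_matrix is None else self.ptv_dose_matrix[:, list(order)]
            ),
            meta=dict(self.meta),
        )
        return p


def generate_candidates(
    nodes: Sequence[Node],
    structures: StructureSet,
    collimators: Sequence[float] = (20.0, 25.0),
    sectors: dict[str, tuple[str, ...]] | None = None,
    beams_per_node: int = 1,
    seed: int = 0,
) -> list[Beam]:
    """Aim candidate beams from allowed nodes at sampled PTV points.

    ``sectors`` maps each PTV label to the node sectors allowed to
    target it (``DIVIDED_SECTORS`` for divided-node-set planning; all
    sectors by default).  Deterministic for a fixed seed.
    """
    if not nodes:
        raise ValueError("node list is empty")
    sectors = dict(FULL_SECTORS if sectors is None else sectors)
    rng = np.random.default_rng(seed)
    candidates: list[Beam] = []
    bid = 0
    for target_label in ("RPTV", "LPTV"):
        allowed = sectors[target_label]
        sel = [nd for nd in nodes if nd.sector in allowed]
        if not sel:
            raise ValueError(
                f"no nodes available in sectors {allowed} for {target_label}"
            )
        ptv: Mask = getattr(structures, target_label)
        centers = ptv.centers_mm()
        for nd in sel:
            picks = rng.integers(0, len(centers), size=beams_per_node)
            for i in picks:
                candidates.append(
                    Beam(
                        node=nd,
                        target_point_mm=centers[i],
                        collimator_diameter_mm=float(rng.choice(collimators)),
                        mu=0.0,
                        id=bid,
                        target_label=target_label,
                    )
                )
                bid += 1
    return candidates


def _dose_matrix(beams: list[Beam], points: np.ndarray, body: Mask) -> np.ndarray:
    """(points, beams) per-MU dose matrix; beams missing the body give zeros."""
    A = np.zeros((len(points), len(beams)))
    for j, b in enumerate(beams):
        entry = body_entry_depth(b, body)
        if entry is None:
            continue
        A[:, j] = dose_per_mu_at_points(b, points, entry)
    return A


def coverage_at(dose: DoseGrid, mask: Mask, dose_gy: float) -> float:
    """Fraction of mask voxels receiving at least ``dose_gy``."""
    v = dose.values[mask.voxels]
    if v.size == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    return float(np.mean(v >= dose_gy))


def _coverage_scale(ptv_dose: np.ndarray, rx: Prescription, headroom: float = 1.002) -> float:
    """Scale factor pinning the coverage quantile to the prescription."""
    n = len(ptv_dose)
    k_cover = int(np.ceil(rx.min_coverage * n))  # voxels that must reach dose
    threshold = np.sort(ptv_dose)[n - k_cover]
    if threshold <= 0:
        raise ValueError("candidate set cannot cover the PTV (zero-dose voxels)")
    return headroom * rx.dose_gy / threshold


def _nnls(A: np.ndarray, b: np.ndarray, x0=None, n_iter: int = 400) -> np.ndarray:
    """Nonnegative least squares by accelerated projected gradient (FISTA).

    Deterministic, warm-startable, and fast for the dense tall systems
    the optimizer builds (thousands of voxels by hundreds of beams).
    """
    AtA = A.T @ A
    Atb = A.T @ b
    # Lipschitz constant via power iteration on A^T A
    v = np.full(A.shape[1], 1.0 / np.sqrt(A.shape[1]))
    for _ in range(25):
        v = AtA @ v
        n = np.linalg.norm(v)
        if n == 0:
            return np.zeros(A.shape[1])
        v /= n
    L = float(v @ (AtA @ v)) * 1.02
    x = np.zeros(A.shape[1]) if x0 is None else np.maximum(np.asarray(x0, float), 0.0)
    y, t = x.copy(), 1.0
    for _ in range(n_iter):
        x_new = np.maximum(y - (AtA @ y - Atb) / L, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        y = x_new + ((t - 1) / t_new) * (x_new - x)
        x, t = x_new, t_new
    return x


def optimize_mu(
    candidates: list[Beam],
    structures: StructureSet,
    rx: Prescription,
    constraints: ConstraintSet,
    seed: int = 0,
    prune_fraction: float = 0.01,
    oar_iterations: int = 6,
    mode: str = "regular",
    dose_evaluator=None,
    dose_builder=None,
) -> Plan:
    """Fit nonnegative MU so the PTVs meet the prescription under the limits.

    Returns a :class:`Plan` whose ``feasible`` flag and
    ``constraint_report`` say whether the hard organ-at-risk limits held
    after the coverage rescale; an infeasible geometry yields a
    structured report, never a silent failure.

    ``dose_evaluator(beams, points) -> (points, beams)`` and
    ``dose_builder(beams) -> DoseGrid`` default to the static dose model;
    the 4D optimizer swaps in phase-accumulated versions.
    """
    for label in ("RPTV", "LPTV"):
        if not any(b.target_label == label for b in candidates):
            raise ValueError(f"no candidate beams target {label}")
    grid = structures.RPTV.grid
    body = structures.body
    if dose_evaluator is None:
        dose_evaluator = lambda beams, pts: _dose_matrix(beams, pts, body)
    if dose_builder is None:
        dose_builder = lambda beams: plan_dose(beams, grid, body)

    ptv = structures.ptv_combined
    ptv_idx = ptv.indices()
    ptv_pts = grid.voxel_centers(ptv_idx)
    A_ptv = dose_evaluator(candidates, ptv_pts)

    def own_phase_mask(beams: list[Beam]) -> np.ndarray:
        """(voxels, beams) bool: beam belongs to the voxel's own target
        group (divided mode prescribes each lesion from its own node set)."""
        rows_r = structures.RPTV.voxels[ptv_idx[:, 0], ptv_idx[:, 1], ptv_idx[:, 2]]
        cols_r = np.array([b.target_label == "RPTV" for b in beams])
        return np.where(rows_r[:, None], cols_r[None, :], ~cols_r[None, :])

    if mode == "divided":
        A_fit = A_ptv * own_phase_mask(candidates)
    else:
        A_fit = A_ptv

    # one-sided penalty points: organ-at-risk voxels near the targets, with
    # guide doses safely under their tightest limit, plus a normal-tissue
    # shell around the PTVs to keep hot spots and spill under control
    oar_labels = [o for o in ("esophagus", "bronchial_tree", "LCA") if hasattr(structures, o)]
    pen_pts, pen_guide = [], []
    for o in oar_labels:
        m: Mask = getattr(structures, o)
        pts = m.centers_mm()
        near = np.linalg.norm(pts - ptv_pts.mean(axis=0), axis=1) < 80.0
        pts = pts[near]
        doses = [L.dose_gy for L in constraints.for_organ(o) if L.kind == "vx"]
        doses += [L.limit for L in constraints.for_organ(o) if L.kind == "dmax"]
        guide = 0.85 * min(doses) if doses else 0.5 * rx.dose_gy
        pen_pts.append(pts)
        pen_guide.append(np.full(len(pts), guide))
    shell = dilate_mask(ptv, 25.0).voxels & ~dilate_mask(ptv, 4.0).voxels & body.voxels
    shell_pts = grid.voxel_centers(np.argwhere(shell))
    rng = np.random.default_rng(seed)
    if len(shell_pts) > 4000:
        shell_pts = shell_pts[rng.choice(len(shell_pts), 4000, replace=False)]
    pen_pts.append(shell_pts)
    pen_guide.append(np.full(len(shell_pts), 0.9 * rx.dose_gy))
    pen_pts = np.concatenate(pen_pts) if pen_pts else np.empty((0, 3))
    pen_guide = np.concatenate(pen_guide) if pen_guide else np.empty(0)
    A_oar = dose_evaluator(candidates, pen_pts)

    def refit(A_t, A_p, w0):
        """Iterative reweighting: boost underdosed target voxels and
        penalty points above their guide (one-sided on both fronts)."""
        w = w0
        wt = np.ones(len(b_ptv))
        for _ in range(oar_iterations):
            d_ptv = A_t @ w
            cold = d_ptv < rx.dose_gy
            wt[cold] = np.minimum(wt[cold] * (rx.dose_gy / np.maximum(d_ptv[cold], 1.0)) ** 1.5, 30.0)
            d_pen = A_p @ w
            hot = d_pen > pen_guide
            if hot.any():
                pw = 5.0 * d_pen[hot] / pen_guide[hot]
                A_stack = np.vstack([A_t * wt[:, None], A_p[hot] * pw[:, None]])
                b_stack = np.concatenate([b_ptv * wt, pen_guide[hot] * pw])
            else:
                A_stack = A_t * wt[:, None]
                b_stack = b_ptv * wt
            w = _nnls(A_stack, b_stack, x0=w)
        return w

    b_ptv = np.full(len(ptv_pts), 1.04 * rx.dose_gy)
    w = refit(A_fit, A_oar, _nnls(A_fit, b_ptv))

    # prune trivially weighted beams and re-fit the survivors
    if w.max() <= 0:
        raise ValueError("optimizer returned an all-zero plan")
    keep = np.flatnonzero(w >= prune_fraction * w.max())
    A_fit_k, A_oar_k = A_fit[:, keep], A_oar[:, keep]
    w_k = refit(A_fit_k, A_oar_k, w[keep])
    # a re-fit can zero out further beams; drop them too
    keep2 = np.flatnonzero(w_k >= prune_fraction * max(w_k.max(), 1e-12))
    keep = keep[keep2]
    w_k = w_k[keep2]
    A_ptv_k = A_ptv[:, keep]
    A_fit_k = A_fit_k[:, keep2]

    kept_cands = [candidates[i] for i in keep]
    if mode == "divided":
        # sequential per-lesion delivery: each lesion is prescribed from
        # its own node-set beams, so every covered voxel reaches the dose
        # within its own delivery phase (cross-phase dose is a bonus)
        for label in ("RPTV", "LPTV"):
            grp = np.array([b.target_label == label for b in kept_cands])
            rows = getattr(structures, label).voxels[
                ptv_idx[:, 0], ptv_idx[:, 1], ptv_idx[:, 2]
            ]
            if grp.any() and rows.any():
                own = A_fit_k[np.ix_(rows, grp)] @ w_k[grp]
                w_k[grp] *= _coverage_scale(own, rx)
    else:
        w_k = w_k * _coverage_scale(A_ptv_k @ w_k, rx)

    beams = []
    for j, idx in enumerate(keep):
        b = candidates[idx]
        beams.append(
            Beam(
                node=b.node,
                target_point_mm=b.target_point_mm,
                collimator_diameter_mm=b.collimator_diameter_mm,
                mu=float(w_k[j]),
                id=b.id,
                target_label=b.target_label,
            )
        )
    order = _regular_order(beams)
    beams = [beams[i] for i in order]
    mu = np.array([b.mu for b in beams])
    A_final = A_ptv_k[:, order] if len(order) else A_ptv_k

    dose = dose_builder(beams)
    cov = coverage_at(dose, ptv, rx.dose_gy)
    report = check_constraints(dose, structures, constraints)
    feasible = cov >= rx.min_coverage and report["hard_ok"]

    return Plan(
        beams=beams,
        prescription=rx,
        seed=seed,
        mode=mode,
        dose=dose,
        coverage=cov,
        feasible=feasible,
        constraint_report=report,
        ptv_voxel_indices=ptv_idx,
        ptv_dose_matrix=A_final * mu[None, :],
        meta={
            "n_candidates": len(candidates),
            "prescription_isodose": rx.dose_gy / max(dose.values.max(), 1e-9),
        },
    )


def _regular_order(beams: list[Beam]) -> list[int]:
    """Standard delivery order: one contiguous visit per node, nodes in a
    nearest-neighbor hemisphere traversal."""
    if not beams:
        return []
    by_node: dict[int, list[int]] = {}
    for i, b in enumerate(beams):
        by_node.setdefault(b.node.id, []).append(i)
    node_pos = {b.node.id: b.node.position for b in beams}
    remaining = sorted(by_node)
    path = [remaining.pop(0)]
    while remaining:
        last = node_pos[path[-1]]
        nxt = min(remaining, key=lambda nid: (float(np.linalg.norm(node_pos[nid] - last)), nid))
        remaining.remove(nxt)
        path.append(nxt)
    return [i for nid in path for i in by_node[nid]]


def block_probe(
    candidates: list[Beam], probe: Mask
) -> tuple[list[Beam], list[Beam]]:
    """Split beams into (kept, blocked) by intersection with the probe.

    A beam is blocked iff its source-to-target segment passes through
    any probe voxel (exact traversal).  An empty probe keeps everything.
    """
    if not probe.voxels.any():
        warnings.warn("probe mask is empty; no beams blocked", stacklevel=2)
        return list(candidates), []
    kept, blocked = [], []
    for b in candidates:
        t_len = float(np.linalg.norm(b.target_point_mm - b.source))
        idx, _ = ray_grid_voxels(probe.grid, b.source, b.direction, t_max=t_len)
        hit = len(idx) > 0 and probe.voxels[idx[:, 0], idx[:, 1], idx[:, 2]].any()
        (blocked if hit else kept).append(b)
    return kept, blocked


def check_constraints(
    dose: DoseGrid, structures: StructureSet, c: ConstraintSet
) -> dict:
    """Evaluate every limit; report measured Dmax / VxGy and pass flags.

    Organs without a mask in the structure set are marked
    ``not evaluated`` and do not fail the plan.
    """
    if dose.grid.shape != structures.body.grid.shape:
        raise ValueError("dose grid does not match the structure grid")
    masks = structures.as_dict()
    report: dict = {"organs": {}, "hard_ok": True, "soft_ok": True}
    vox_cc = dose.grid.voxel_volume_mm3 / 1000.0
    for organ in c.organs:
        entry: dict = {"evaluated": organ in masks, "checks": []}
        if organ in masks:
            v = dose.values[masks[organ].voxels]
            dmax = float(v.max()) if v.size else 0.0
            entry["dmax_gy"] = dmax
            for L in c.for_organ(organ):
                if L.kind == "dmax":
                    measured = dmax
                else:
                    measured = float(np.sum(v >= L.dose_gy)) * vox_cc
                passed = measured < L.limit if L.severity == "soft" else measured <= L.limit
                entry["checks"].append(
                    {
                        "name": L.name,
                        "measured": measured,
                        "limit": L.limit,
                        "severity": L.severity,
                        "passed": bool(passed),
                    }
                )
                if not passed:
                    report["hard_ok" if L.severity == "hard" else "soft_ok"] = False
        report["organs"][organ] = entry
    return report
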