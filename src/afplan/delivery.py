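"""Delivery timelines, the EFTT model, and beam-sequence re-sorting.

The estimated fraction treatment time (EFTT, minutes) is an additive
model of the delivery overheads:

    EFTT = nodes / 4 + beams / 20          (robot and collimator motion)
         + MU / output                     (beam-on time)
         + beams / images_per_beam / 10    (imaging)
         + beams / 15                      (motion-tracking overhead)

Patient setup is not included.  The per-beam decomposition used by
:func:`build_timeline` (0.25 min per node visit, 0.05 min collimator
change per beam, MU/output beam-on, 1/(10*ipb) imaging, 1/15 tracking)
allocates exactly these totals, with the node count replaced by the
number of node *visits* so that re-sorted sequences, which revisit
nodes, correctly cost extra travel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dose_engine import Beam, ray_structure_entries
from .phantom import StructureSet
from .planner import Plan

__all__ = [
    "PHASE_ORDER",
    "TimelineParams",
    "TimelineEvent",
    "DeliveryTimeline",
    "compute_eftt",
    "build_timeline",
    "classify_beam",
    "resort_plan",
    "split_by_target",
    "sequence_divided",
]

NODE_VISIT_MIN = 0.25
IRIS_MIN = 0.05
IMAGING_BASE_MIN = 0.1
SYNCHRONY_MIN = 1.0 / 15.0

#: Delivery phases for two-target re-sorting, in delivery order.
PHASE_ORDER = ("R_only", "R_then_L", "L_then_R", "L_only", "neither")


@dataclass(frozen=True)
class TimelineParams:
    """Machine throughput parameters of the delivery-time model."""

    dose_output_mu_per_min: float = 800.0
    images_per_beam: float = 1.0
    synchrony_on: bool = True

    def __post_init__(self) -> None:
        if self.dose_output_mu_per_min <= 0:
            raise ValueError("dose output must be positive")
        if self.images_per_beam <= 0:
            raise ValueError("images_per_beam must be positive")


def compute_eftt(
    n_nodes: int, n_beams: int, total_mu: float, p: TimelineParams
) -> float:
    """EFTT in minutes from node/beam counts and total MU (exact formula)."""
    if n_nodes < 0 or n_beams < 0 or total_mu < 0:
        raise ValueError("counts and MU must be nonnegative")
    t = (
        n_nodes / 4.0
        + n_beams / 20.0
        + total_mu / p.dose_output_mu_per_min
        + n_beams / p.images_per_beam / 10.0
        + (n_beams / 15.0 if p.synchrony_on else 0.0)
    )
    return float(t)


@dataclass
class TimelineEvent:
    """One beam's slot: components in minutes, beam-on marked explicitly."""

    beam_id: int
    node_id: int
    start_min: float
    motion: float
    imaging: float
    beam_on: float
    synchrony: float

    @property
    def end_min(self) -> float:
        return self.start_min + self.motion + self.imaging + self.beam_on + self.synchrony

    @property
    def beam_on_interval(self) -> tuple[float, float]:
        t0 = self.start_min + self.motion + self.imaging
        return (t0, t0 + self.beam_on)


@dataclass
class DeliveryTimeline:
    """Contiguous per-beam events starting at t = 0; sums to the EFTT."""

    events: list[TimelineEvent]
    beams: list[Beam]
    params: TimelineParams
    n_node_visits: int

    @property
    def eftt_min(self) -> float:
        return self.events[-1].end_min if self.events else 0.0

    def beam_on_intervals(self) -> np.ndarray:
        """(n_beams, 2) start/end minutes of each beam-on segment."""
        return np.array([e.beam_on_interval for e in self.events])


def build_timeline(
    plan: Plan,
    p: TimelineParams = TimelineParams(),
    order: Optional[Sequence[int]] = None,
) -> DeliveryTimeline:
    """Allocate per-beam durations along the plan's delivery order.

    A node visit costs 0.25 min whenever the node differs from the
    previous beam's node; every beam adds the collimator, imaging,
    beam-on and (optional) tracking components.  The total equals
    :func:`compute_eftt` with the node count set to the visit count.
    """
    if not plan.beams:
        raise ValueError("plan has no beams")
    beams = plan.beams if order is None else [plan.beams[i] for i in order]
    events: list[TimelineEvent] = []
    t = 0.0
    visits = 0
    prev_node = None
    for b in beams:
        motion = IRIS_MIN
        if b.node.id != prev_node:
            motion += NODE_VISIT_MIN
            visits += 1
        imaging = IMAGING_BASE_MIN / p.images_per_beam
        beam_on = b.mu / p.dose_output_mu_per_min
        synchrony = SYNCHRONY_MIN if p.synchrony_on else 0.0
        ev = TimelineEvent(
            beam_id=b.id,
            node_id=b.node.id,
            start_min=t,
            motion=motion,
            imaging=imaging,
            beam_on=beam_on,
            synchrony=synchrony,
        )
        events.append(ev)
        t = ev.end_min
        prev_node = b.node.id
    return DeliveryTimeline(events=events, beams=list(beams), params=p, n_node_visits=visits)


def classify_beam(b: Beam, structures: StructureSet) -> str:
    """Phase label from the order in which the central axis meets the PTVs."""
    entries = ray_structure_entries(b, structures, labels=["RPTV", "LPTV"])
    labels = [lab for lab, _ in entries]
    if labels == ["RPTV"]:
        return "R_only"
    if labels == ["LPTV"]:
        return "L_only"
    if labels == ["RPTV", "LPTV"]:
        return "R_then_L"
    if labels == ["LPTV", "RPTV"]:
        return "L_then_R"
    return "neither"


def _nn_node_groups(
    indices: list[int], beams: list[Beam], start_pos: Optional[np.ndarray]
) -> list[int]:
    """Order beams within a phase: one visit per node, nearest-neighbor
    node traversal from ``start_pos`` (deterministic tie-break on id)."""
    by_node: dict[int, list[int]] = {}
    node_pos: dict[int, np.ndarray] = {}
    for i in indices:
        by_node.setdefault(beams[i].node.id, []).append(i)
        node_pos[beams[i].node.id] = beams[i].node.position
    remaining = sorted(by_node)
    out: list[int] = []
    pos = start_pos
    while remaining:
        if pos is None:
            nxt = remaining[0]
        else:
            nxt = min(
                remaining,
                key=lambda nid: (float(np.linalg.norm(node_pos[nid] - pos)), nid),
            )
        remaining.remove(nxt)
        out.extend(by_node[nxt])
        pos = node_pos[nxt]
    return out


def resort_plan(plan: Plan, labels: Sequence[str]) -> Plan:
    """Re-sort delivery into contiguous phases R_only, R_then_L, L_then_R,
    L_only (then any beams missing both PTVs).

    The beam multiset, MU, and final dose are untouched — only the order
    changes.  Nodes contributing to several phases are revisited, so the
    re-sorted EFTT can only grow.  Idempotent: re-sorting a re-sorted
    plan reproduces it.
    """
    if len(labels) != len(plan.beams):
        raise ValueError("labels must cover every beam")
    order: list[int] = []
    prev_pos: Optional[np.ndarray] = None
    for phase in PHASE_ORDER:
        idx = [i for i, lab in enumerate(labels) if lab == phase]
        if not idx:
            continue
        grp = _nn_node_groups(idx, plan.beams, prev_pos)
        order.extend(grp)
        prev_pos = plan.beams[grp[-1]].node.position
    out = plan.reordered(order)
    out.mode = "resorted"
    return out


def split_by_target(plan: Plan) -> tuple[Plan, Plan]:
    """Split a jointly optimized divided-mode plan into its RPTV and LPTV
    sub-plans (by the target each beam was aimed at)."""
    idx_r = [i for i, b in enumerate(plan.beams) if b.target_label == "RPTV"]
    idx_l = [i for i, b in enumerate(plan.beams) if b.target_label == "LPTV"]

    def sub(indices: list[int], mode: str) -> Plan:
        return Plan(
            beams=[plan.beams[i] for i in indices],
            prescription=plan.prescription,
            seed=plan.seed,
            mode=mode,
            ptv_voxel_indices=plan.ptv_voxel_indices,
            ptv_dose_matrix=(
                None if plan.ptv_dose_matrix is None else plan.ptv_dose_matrix[:, indices]
            ),
            meta=dict(plan.meta),
        )

    return sub(idx_r, "divided-R"), sub(idx_l, "divided-L")


def sequence_divided(
    plan_R: Plan, plan_L: Plan, p: TimelineParams = TimelineParams()
) -> tuple[Plan, DeliveryTimeline]:
    """Sequential divided-node-set delivery: all RPTV beams, then all LPTV.

    The RPTV sub-plan must use only anterior/right-lateral nodes and the
    LPTV sub-plan only left-lateral/anterior nodes; a violation is
    rejected.  The combined EFTT is the sum of the two sub-timelines
    (shared anterior nodes are visited once per sub-plan, per the visit
    model).
    """
    for b in plan_R.beams:
        if b.node.sector not in ("anterior", "right_lateral"):
            raise ValueError(
                f"RPTV beam {b.id} uses a {b.node.sector} node; divided mode forbids it"
            )
    for b in plan_L.beams:
        if b.node.sector not in ("anterior", "left_lateral"):
            raise ValueError(
                f"LPTV beam {b.id} uses a {b.node.sector} node; divided mode forbids it"
            )
    if not plan_L.beams:
        tl = build_timeline(plan_R, p)
        return plan_R, tl
    if not plan_R.beams:
        tl = build_timeline(plan_L, p)
        return plan_L, tl

    tl_R = build_timeline(plan_R, p)
    tl_L = build_timeline(plan_L, p)
    offset = tl_R.eftt_min
    events = list(tl_R.events)
    for e in tl_L.events:
        events.append(
            TimelineEvent(
                beam_id=e.beam_id,
                node_id=e.node_id,
                start_min=e.start_min + offset,
                motion=e.motion,
                imaging=e.imaging,
                beam_on=e.beam_on,
                synchrony=e.synchrony,
            )
        )
    combined_tl = DeliveryTimeline(
        events=events,
        beams=list(plan_R.beams) + list(plan_L.beams),
        params=p,
        n_node_visits=tl_R.n_node_visits + tl_L.n_node_visits,
    )
    same_rows = (
        plan_R.ptv_voxel_indices is not None
        and plan_L.ptv_voxel_indices is not None
        and np.array_equal(plan_R.ptv_voxel_indices, plan_L.ptv_voxel_indices)
    )
    combined = Plan(
        beams=combined_tl.beams,
        prescription=plan_R.prescription,
        seed=plan_R.seed,
        mode="divided",
        dose=plan_R.dose,
        ptv_voxel_indices=plan_R.ptv_voxel_indices,
        ptv_dose_matrix=(
            np.hstack([plan_R.ptv_dose_matrix, plan_L.ptv_dose_matrix])
            if same_rows and plan_R.ptv_dose_matrix is not None
            else None
        ),
        meta={**plan_R.meta, "eftt_R_min": tl_R.eftt_min, "eftt_L_min": tl_L.eftt_min},
    )
    return combined, combined_tl
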