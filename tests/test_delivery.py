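"""EFTT arithmetic, timeline construction, phase classification, re-sorting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afplan import delivery as dlv
from afplan.delivery import (
    PHASE_ORDER,
    DeliveryTimeline,
    TimelineParams,
    build_timeline,
    classify_beam,
    compute_eftt,
    resort_plan,
    sequence_divided,
    split_by_target,
)
from afplan.dose_engine import Beam, Node
from afplan.geometry import Mask, VoxelGrid
from afplan.planner import Plan, Prescription


def _plan(beams, matrix=None):
    n = len(beams)
    return Plan(
        beams=beams,
        prescription=Prescription(),
        ptv_voxel_indices=np.zeros((1, 3), dtype=int) if matrix is not None else None,
        ptv_dose_matrix=matrix,
    )


def _beam(node, mu, bid=0, target="RPTV"):
    return Beam(node, np.array([0.0, 0.0, 0.0]), 25.0, mu, bid, target)


class TestComputeEFTT:
    def test_zero_everything_is_zero(self):
        assert compute_eftt(0, 0, 0.0, TimelineParams()) == 0.0

    def test_hand_arithmetic_example(self):
        # 40/4 + 20/20 + 8000/800 + 20/1/10 + 20/15
        got = compute_eftt(40, 20, 8000.0, TimelineParams(800.0, 1.0, True))
        assert got == pytest.approx(10 + 1 + 10 + 2 + 20 / 15, abs=1e-12)

    def test_synchrony_term_dropped_when_off(self):
        on = compute_eftt(10, 30, 0.0, TimelineParams(800.0, 1.0, True))
        off = compute_eftt(10, 30, 0.0, TimelineParams(800.0, 1.0, False))
        assert on - off == pytest.approx(30 / 15)

    def test_nonpositive_output_rejected(self):
        with pytest.raises(ValueError):
            TimelineParams(dose_output_mu_per_min=0.0)
        with pytest.raises(ValueError):
            compute_eftt(-1, 0, 0.0, TimelineParams())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(0, 200),
        st.integers(0, 400),
        st.floats(0, 5e4),
        st.integers(1, 100),
    )
    def test_monotone_in_each_argument(self, nodes, beams, mu, bump):
        p = TimelineParams()
        base = compute_eftt(nodes, beams, mu, p)
        assert compute_eftt(nodes + bump, beams, mu, p) >= base
        assert compute_eftt(nodes, beams + bump, mu, p) >= base
        assert compute_eftt(nodes, beams, mu + bump, p) >= base


class TestBuildTimeline:
    def test_single_beam_component_sum(self):
        node = Node(0, (0.0, -800.0, 0.0), "anterior")
        tl = build_timeline(_plan([_beam(node, 800.0)]), TimelineParams())
        assert tl.eftt_min == pytest.approx(0.25 + 0.05 + 1.0 + 0.1 + 1 / 15, abs=1e-12)
        assert tl.n_node_visits == 1

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            build_timeline(_plan([]), TimelineParams())

    def test_events_contiguous_from_zero(self, default_timeline):
        evs = default_timeline.events
        assert evs[0].start_min == 0.0
        for a, b in zip(evs, evs[1:]):
            assert b.start_min == pytest.approx(a.end_min, abs=1e-12)

    def test_total_equals_formula_with_visit_count(self, default_plan, default_timeline):
        tl = default_timeline
        expected = compute_eftt(
            tl.n_node_visits, len(tl.events), default_plan.total_mu, tl.params
        )
        assert tl.eftt_min == pytest.approx(expected, abs=1e-9)

    def test_permuting_beams_within_one_node_keeps_eftt(self):
        node = Node(0, (0.0, -800.0, 0.0), "anterior")
        beams = [_beam(node, 100.0, 0), _beam(node, 300.0, 1)]
        a = build_timeline(_plan(beams), TimelineParams())
        b = build_timeline(_plan(beams), TimelineParams(), order=[1, 0])
        assert a.eftt_min == pytest.approx(b.eftt_min, abs=1e-12)

    def test_default_plan_eftt_in_clinical_range(self, default_timeline):
        # single-fraction AF deliveries are reported between 50 and 87 min
        assert 50.0 <= default_timeline.eftt_min <= 87.0

    def test_beam_on_mu_bookkeeping(self, default_plan, default_timeline):
        on = default_timeline.beam_on_intervals()
        total_on = float(np.sum(on[:, 1] - on[:, 0]))
        assert total_on * default_timeline.params.dose_output_mu_per_min == pytest.approx(
            default_plan.total_mu, rel=1e-12
        )


@pytest.fixture(scope="module")
def boxes():
    g = VoxelGrid((40, 10, 10), (2.0, 2.0, 2.0), (0.0, -9.0, -9.0))
    r = np.zeros(g.shape, bool)
    r[5:9] = True
    l = np.zeros(g.shape, bool)
    l[25:29] = True
    return {"RPTV": Mask("RPTV", r, g), "LPTV": Mask("LPTV", l, g)}


class TestClassifyBeam:

    def test_only_lptv_gives_l_only(self, boxes):
        node = Node(0, (60.0, 0.0, 300.0), "anterior")
        b = Beam(node, np.array([54.0, 0.0, 0.0]), 25.0, 0.0)
        assert classify_beam(b, boxes) == "L_only"

    def test_r_before_l_gives_r_then_l(self, boxes):
        node = Node(0, (-300.0, 0.0, 0.0), "anterior")
        b = Beam(node, np.array([80.0, 0.0, 0.0]), 25.0, 0.0)
        assert classify_beam(b, boxes) == "R_then_L"

    def test_miss_gives_neither(self, boxes):
        node = Node(0, (0.0, 300.0, 300.0), "anterior")
        b = Beam(node, np.array([0.0, 300.0, -300.0]), 25.0, 0.0)
        assert classify_beam(b, boxes) == "neither"

    def test_default_plan_labels_match_slab_oracle(self, default_plan, structures):
        from oracles import slab_entry_order

        grid = structures.body.grid
        masks = {"RPTV": structures.RPTV, "LPTV": structures.LPTV}
        expected = {
            (): "neither",
            ("RPTV",): "R_only",
            ("LPTV",): "L_only",
            ("RPTV", "LPTV"): "R_then_L",
            ("LPTV", "RPTV"): "L_then_R",
        }
        for b in default_plan.beams[::4]:
            order = tuple(e[0] for e in slab_entry_order(grid, masks, b.source, b.direction))
            assert classify_beam(b, structures) == expected[order]


class TestResortPlan:
    def _toy_alternating(self):
        """Two nodes, each shooting one RPTV and one LPTV beam: grouping
        by phase forces each node to be visited twice."""
        na = Node(0, (0.0, -800.0, 0.0), "anterior")
        nb = Node(1, (100.0, -790.0, 0.0), "anterior")
        beams = [_beam(na, 100.0, 0), _beam(na, 100.0, 1), _beam(nb, 100.0, 2), _beam(nb, 100.0, 3)]
        labels = ["R_only", "L_only", "R_only", "L_only"]
        return _plan(beams), labels

    def test_phases_contiguous_in_delivery_order(self, default_plan, structures):
        labels = [classify_beam(b, structures) for b in default_plan.beams]
        rs = resort_plan(default_plan, labels)
        rs_labels = [classify_beam(b, structures) for b in rs.beams]
        ranks = [PHASE_ORDER.index(lab) for lab in rs_labels]
        assert ranks == sorted(ranks)

    def test_beam_multiset_preserved(self, default_plan, structures):
        labels = [classify_beam(b, structures) for b in default_plan.beams]
        rs = resort_plan(default_plan, labels)
        assert sorted(b.id for b in rs.beams) == sorted(b.id for b in default_plan.beams)

    def test_idempotent(self, default_plan, structures):
        labels = [classify_beam(b, structures) for b in default_plan.beams]
        rs = resort_plan(default_plan, labels)
        labels2 = [classify_beam(b, structures) for b in rs.beams]
        rs2 = resort_plan(rs, labels2)
        assert [b.id for b in rs2.beams] == [b.id for b in rs.beams]

    def test_eftt_never_decreases(self, default_plan, default_timeline, structures):
        labels = [classify_beam(b, structures) for b in default_plan.beams]
        rs = resort_plan(default_plan, labels)
        tl = build_timeline(rs, default_timeline.params)
        assert tl.eftt_min >= default_timeline.eftt_min - 1e-9

    def test_alternating_shared_node_costs_extra_visits(self):
        plan, labels = self._toy_alternating()
        base = build_timeline(plan, TimelineParams())
        rs = resort_plan(plan, labels)
        tl = build_timeline(rs, TimelineParams())
        assert tl.n_node_visits > base.n_node_visits
        assert tl.eftt_min > base.eftt_min

    def test_labels_must_cover_all_beams(self, default_plan):
        with pytest.raises(ValueError):
            resort_plan(default_plan, ["R_only"])

    def test_final_voxel_dose_invariant(self, default_plan, structures):
        labels = [classify_beam(b, structures) for b in default_plan.beams]
        rs = resort_plan(default_plan, labels)
        before = default_plan.ptv_dose_matrix.sum(axis=1)
        after = rs.ptv_dose_matrix.sum(axis=1)
        assert np.abs(before - after).max() < 1e-12


class TestSequenceDivided:
    def _toy_plans(self):
        na = Node(0, (0.0, -800.0, 0.0), "anterior")
        nr = Node(1, (-700.0, -400.0, 0.0), "right_lateral")
        nl = Node(2, (700.0, -400.0, 0.0), "left_lateral")
        pr = _plan([_beam(nr, 200.0, 0, "RPTV"), _beam(na, 100.0, 1, "RPTV")])
        pl = _plan([_beam(na, 150.0, 2, "LPTV"), _beam(nl, 250.0, 3, "LPTV")])
        return pr, pl

    def test_combined_eftt_is_sum_of_parts(self):
        pr, pl = self._toy_plans()
        p = TimelineParams()
        tr = build_timeline(pr, p)
        tlft = build_timeline(pl, p)
        _, combined = sequence_divided(pr, pl, p)
        assert combined.eftt_min == pytest.approx(tr.eftt_min + tlft.eftt_min, abs=1e-9)

    def test_rptv_fully_delivered_before_lptv(self):
        pr, pl = self._toy_plans()
        plan, tl = sequence_divided(pr, pl, TimelineParams())
        targets = [b.target_label for b in plan.beams]
        assert targets == ["RPTV", "RPTV", "LPTV", "LPTV"]

    def test_empty_lptv_plan_reduces_to_rptv_timeline(self):
        pr, _ = self._toy_plans()
        empty = _plan([])
        plan, tl = sequence_divided(pr, empty, TimelineParams())
        assert tl.eftt_min == build_timeline(pr, TimelineParams()).eftt_min

    def test_sector_violation_rejected(self):
        nl = Node(2, (700.0, -400.0, 0.0), "left_lateral")
        bad_r = _plan([_beam(nl, 100.0, 0, "RPTV")])
        ok_l = _plan([_beam(nl, 100.0, 1, "LPTV")])
        with pytest.raises(ValueError, match="left_lateral"):
            sequence_divided(bad_r, ok_l, TimelineParams())

    def test_split_by_target_partitions_divided_plan(self, divided_delivery):
        plan, _ = divided_delivery
        pr, pl = split_by_target(plan)
        assert len(pr.beams) + len(pl.beams) == len(plan.beams)
        assert all(b.target_label == "RPTV" for b in pr.beams)
        assert all(b.target_label == "LPTV" for b in pl.beams)

    def test_divided_dose_conserved_vs_merged(self, divided_delivery):
        plan, _ = divided_delivery
        pr, pl = split_by_target(plan)
        merged = np.hstack([pr.ptv_dose_matrix, pl.ptv_dose_matrix]).sum(axis=1)
        assert np.abs(merged - plan.ptv_dose_matrix.sum(axis=1)).max() < 1e-9
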