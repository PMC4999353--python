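"""DVH metrics, file I/O, run configuration, and the pipeline orchestrator.

Volumes are written as NIfTI (nibabel) with the grid affine, tabular
artifacts (beam lists, timelines, DVH and RDR tables) as CSV via
pandas, and reports as JSON.  ``run_pipeline`` chains phantom ->
candidates -> plan -> timeline -> RDR (plus optional probe-blocking and
4D comparisons) deterministically from one seeded config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import delivery as dlv
from . import motion4d as m4d
from . import planner as pln
from . import rdr as rdrmod
from .dose_engine import Beam, DoseGrid, Node, make_nodes, node_sector
from .geometry import Mask, VoxelGrid
from .phantom import PhantomSpec, StructureSet, generate_phantom

__all__ = [
    "DVHCurve",
    "RunConfig",
    "dvh",
    "run_pipeline",
    "write_mask",
    "read_mask",
    "write_dose",
    "read_dose",
    "beams_to_csv",
    "beams_from_csv",
    "timeline_to_csv",
]

log = logging.getLogger("afplan")


# ---------------------------------------------------------------------------
# DVH


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``volume_cc[i]`` is the volume receiving at least ``dose_gy[i]``
    ("X Gy or more" — inclusive), so the curve is monotone
    non-increasing and starts at the structure volume.
    """

    label: str
    dose_gy: np.ndarray
    volume_cc: np.ndarray
    volume_pct: np.ndarray

    def v_at(self, dose_gy: float) -> float:
        """Volume (cc) receiving >= dose_gy, from the stored samples."""
        i = int(np.searchsorted(self.dose_gy, dose_gy, side="left"))
        return float(self.volume_cc[min(i, len(self.volume_cc) - 1)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": self.label,
                "dose_gy": self.dose_gy,
                "volume_cc": self.volume_cc,
                "volume_pct": self.volume_pct,
            }
        )


def dvh(dose: DoseGrid, mask: Mask, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH with inclusive >= thresholds at bin edges."""
    if not mask.voxels.any():
        raise ValueError(f"mask {mask.label!r} is empty")
    if dose.grid.shape != mask.grid.shape:
        raise ValueError("dose and mask grids differ")
    v = dose.values[mask.voxels]
    vox_cc = dose.grid.voxel_volume_mm3 / 1000.0
    edges = np.arange(0.0, float(v.max()) + 2 * bin_width_gy, bin_width_gy)
    # voxels with dose >= edge, for every edge
    counts = len(v) - np.searchsorted(np.sort(v), edges, side="left")
    vol_cc = counts * vox_cc
    return DVHCurve(
        label=mask.label,
        dose_gy=edges,
        volume_cc=vol_cc,
        volume_pct=100.0 * vol_cc / (len(v) * vox_cc),
    )


# ---------------------------------------------------------------------------
# volume / table I/O


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing_mm)
    aff[:3, 3] = grid.origin_mm
    return aff


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "") -> Mask:
    img = nib.load(str(path))
    aff = img.affine
    grid = VoxelGrid(
        tuple(img.shape), tuple(np.diag(aff)[:3]), tuple(aff[:3, 3])
    )
    return Mask(label or Path(path).stem, np.asarray(img.dataobj) > 0, grid)


def write_dose(dose: DoseGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), _affine(dose.grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_dose(path: str | Path) -> DoseGrid:
    img = nib.load(str(path))
    aff = img.affine
    grid = VoxelGrid(tuple(img.shape), tuple(np.diag(aff)[:3]), tuple(aff[:3, 3]))
    return DoseGrid(np.asarray(img.dataobj, dtype=np.float64), grid)


def beams_to_csv(beams: list[Beam], path: str | Path) -> None:
    rows = []
    for b in beams:
        s = b.source
        t = b.target_point_mm
        rows.append(
            {
                "id": b.id,
                "node_id": b.node.id,
                "node_sector": b.node.sector,
                "source_x_mm": s[0],
                "source_y_mm": s[1],
                "source_z_mm": s[2],
                "target_x_mm": t[0],
                "target_y_mm": t[1],
                "target_z_mm": t[2],
                "collimator_mm": b.collimator_diameter_mm,
                "mu": b.mu,
                "target_label": b.target_label,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def beams_from_csv(path: str | Path) -> list[Beam]:
    df = pd.read_csv(path)
    beams = []
    for _, r in df.iterrows():
        node = Node(
            id=int(r["node_id"]),
            position_mm=(r["source_x_mm"], r["source_y_mm"], r["source_z_mm"]),
            sector=str(r["node_sector"]),
        )
        beams.append(
            Beam(
                node=node,
                target_point_mm=np.array(
                    [r["target_x_mm"], r["target_y_mm"], r["target_z_mm"]]
                ),
                collimator_diameter_mm=float(r["collimator_mm"]),
                mu=float(r["mu"]),
                id=int(r["id"]),
                target_label=str(r.get("target_label", "")),
            )
        )
    return beams


def timeline_to_csv(tl: dlv.DeliveryTimeline, path: str | Path) -> None:
    rows = [
        {
            "beam_id": e.beam_id,
            "node_id": e.node_id,
            "start_min": e.start_min,
            "motion_min": e.motion,
            "imaging_min": e.imaging,
            "beam_on_min": e.beam_on,
            "synchrony_min": e.synchrony,
            "end_min": e.end_min,
        }
        for e in tl.events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run.

    The config is echoed verbatim into every report so results are
    self-describing.
    """

    seed: int = 42
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    grid_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    esophagus_class: str = "central-away"
    margin_mm: float = 3.0
    prescription_gy: float = 25.0
    min_coverage: float = 0.99
    n_nodes: int = 100
    beams_per_node: int = 1
    collimators_mm: tuple[float, ...] = (20.0, 25.0)
    deliveries: tuple[str, ...] = ("regular", "resorted", "divided")
    probe_on: bool = False
    fourd_on: bool = False
    rdr_windows_min: tuple[int, ...] = (45,)
    dose_output_mu_per_min: float = 800.0
    images_per_beam: float = 1.0
    synchrony_on: bool = True
    motion: dict = Field(default_factory=dict)
    output_dir: Optional[str] = None

    def phantom_spec(self, with_probe: bool = False) -> PhantomSpec:
        return PhantomSpec(
            shape=self.grid_shape,
            spacing_mm=self.grid_spacing_mm,
            esophagus_class=self.esophagus_class,
            margin_mm=self.margin_mm,
            with_probe=with_probe or self.probe_on,
            seed=self.seed,
        )

    def prescription(self) -> pln.Prescription:
        return pln.Prescription(self.prescription_gy, self.min_coverage)

    def timeline_params(self) -> dlv.TimelineParams:
        return dlv.TimelineParams(
            self.dose_output_mu_per_min, self.images_per_beam, self.synchrony_on
        )

    def motion_spec(self) -> m4d.MotionSpec:
        return m4d.MotionSpec(**self.motion)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


# ---------------------------------------------------------------------------
# pipeline


def _rdr_rows(
    plan: pln.Plan,
    timeline: dlv.DeliveryTimeline,
    structures: StructureSet,
    windows: tuple[int, ...],
    threshold_gy: float,
    mode: str,
) -> list[dict]:
    series = rdrmod.cumulative_series(
        timeline, plan.ptv_dose_matrix, plan.ptv_voxel_indices
    )
    rows = []
    for w in windows:
        rmap = rdrmod.compute_rdr(series, w)
        cov = rdrmod.rdr_coverage(rmap, threshold_gy, structures)
        for target, value in cov.items():
            rows.append(
                {
                    "mode": mode,
                    "window_min": int(w),
                    "threshold_gy": threshold_gy,
                    "target": target,
                    "coverage": value,
                    "eftt_min": timeline.eftt_min,
                }
            )
    return rows


def _plan_summary(plan: pln.Plan, timeline=None) -> dict:
    out = {
        "coverage": plan.coverage,
        "feasible": plan.feasible,
        "n_beams": plan.n_beams,
        "n_nodes": plan.n_nodes,
        "total_mu": plan.total_mu,
        "prescription_isodose": plan.meta.get("prescription_isodose"),
    }
    if timeline is not None:
        out["eftt_min"] = timeline.eftt_min
        out["n_node_visits"] = timeline.n_node_visits
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured planning study end-to-end; returns the summary.

    Stage failures are logged with the stage name and re-raised after
    the partial summary is written (when an output dir is set).
    """
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    cfg_echo = json.loads(cfg.model_dump_json())
    cfg_echo.pop("output_dir", None)  # keep summaries path-independent
    summary: dict = {"config": cfg_echo}
    stage = "phantom"
    try:
        grid, structures = generate_phantom(cfg.phantom_spec())
        summary["phantom"] = {
            "esophagus_class": structures.esophagus_class,
            "lesion_R_cc": structures.lesion_R.volume_cc,
            "lesion_L_cc": structures.lesion_L.volume_cc,
            "RPTV_cc": structures.RPTV.volume_cc,
            "LPTV_cc": structures.LPTV.volume_cc,
            "PTV_combined_cc": structures.ptv_combined.volume_cc,
        }
        if outdir:
            for name, m in structures.as_dict().items():
                write_mask(m, outdir / f"{name}.nii.gz")
            (outdir / "structures.json").write_text(
                json.dumps(
                    {
                        "labels": sorted(structures.as_dict()),
                        "septum_point_mm": structures.septum_point_mm.tolist(),
                        "esophagus_class": structures.esophagus_class,
                        "seed": cfg.seed,
                        "frame": "LPS-like: +x left, +y posterior, +z superior",
                    },
                    indent=1,
                    sort_keys=True,
                )
            )

        stage = "planning"
        rx = cfg.prescription()
        constraints = pln.ConstraintSet()
        centroid = structures.ptv_combined.centers_mm().mean(axis=0)
        nodes = make_nodes(cfg.n_nodes, centroid)
        tp = cfg.timeline_params()
        threshold = rx.dose_gy

        candidates = pln.generate_candidates(
            nodes,
            structures,
            collimators=cfg.collimators_mm,
            beams_per_node=cfg.beams_per_node,
            seed=cfg.seed,
        )
        plan = pln.optimize_mu(candidates, structures, rx, constraints, seed=cfg.seed)
        timeline = dlv.build_timeline(plan, tp)
        summary["plans"] = {"regular": _plan_summary(plan, timeline)}
        summary["constraints"] = plan.constraint_report
        rdr_rows: list[dict] = []
        if "regular" in cfg.deliveries:
            stage = "rdr-regular"
            rdr_rows += _rdr_rows(plan, timeline, structures, cfg.rdr_windows_min, threshold, "regular")

        if "resorted" in cfg.deliveries:
            stage = "rdr-resorted"
            labels = [dlv.classify_beam(b, structures) for b in plan.beams]
            resorted = dlv.resort_plan(plan, labels)
            tl_rs = dlv.build_timeline(resorted, tp)
            summary["plans"]["resorted"] = _plan_summary(resorted, tl_rs)
            rdr_rows += _rdr_rows(resorted, tl_rs, structures, cfg.rdr_windows_min, threshold, "resorted")

        if "divided" in cfg.deliveries:
            stage = "rdr-divided"
            div_cands = pln.generate_candidates(
                nodes,
                structures,
                collimators=cfg.collimators_mm,
                sectors=pln.DIVIDED_SECTORS,
                beams_per_node=cfg.beams_per_node,
                seed=cfg.seed,
            )
            div_plan = pln.optimize_mu(
                div_cands, structures, rx, constraints, seed=cfg.seed, mode="divided"
            )
            plan_R, plan_L = dlv.split_by_target(div_plan)
            combined, tl_div = dlv.sequence_divided(plan_R, plan_L, tp)
            combined.coverage = div_plan.coverage
            combined.feasible = div_plan.feasible
            combined.meta.update(div_plan.meta)
            summary["plans"]["divided"] = _plan_summary(combined, tl_div)
            rdr_rows += _rdr_rows(combined, tl_div, structures, cfg.rdr_windows_min, threshold, "divided")
        summary["rdr"] = rdr_rows
        if outdir and rdr_rows:
            pd.DataFrame(rdr_rows).to_csv(outdir / "rdr.csv", index=False)
        if outdir:
            beams_to_csv(plan.beams, outdir / "plan_regular.csv")
            timeline_to_csv(timeline, outdir / "timeline_regular.csv")
            write_dose(plan.dose, outdir / "dose_regular.nii.gz")

        if cfg.probe_on:
            stage = "probe"
            _, structures_p = generate_phantom(cfg.phantom_spec(with_probe=True))
            kept, blocked = pln.block_probe(candidates, structures_p.probe)
            plan_blocked = pln.optimize_mu(
                kept, structures_p, rx, constraints, seed=cfg.seed, mode="probe-blocked"
            )
            blocked_nodes = {b.node.id for b in blocked} - {b.node.id for b in kept}
            summary["probe"] = {
                "n_blocked_beams": len(blocked),
                "n_fully_blocked_nodes": len(blocked_nodes),
                "coverage_without_block": plan.coverage,
                "coverage_with_block": plan_blocked.coverage,
                "coverage_delta_pp": 100.0 * (plan_blocked.coverage - plan.coverage),
                "constraints_with_block": plan_blocked.constraint_report,
            }

        if cfg.fourd_on:
            stage = "fourd"
            mspec = cfg.motion_spec()
            fields = m4d.make_fields(mspec, "respiratory", structures)
            acc, rep4d = m4d.accumulate_4d(
                plan, fields, structures, structures.septum_point_mm
            )
            red_static = m4d.coverage_reduction(plan.dose, acc, structures, rx)
            plan4d = m4d.optimize_4d(
                candidates,
                fields,
                structures,
                rx,
                constraints,
                structures.septum_point_mm,
                seed=cfg.seed,
            )
            red_4d = m4d.coverage_reduction(plan.dose, plan4d.dose, structures, rx)
            summary["fourd"] = {
                "surrogate": rep4d["surrogate_shift_mm"],
                "static_plan_reduction": red_static,
                "optimized_4d_reduction": red_4d,
                "plan4d": _plan_summary(plan4d),
            }
    except Exception:
        log.exception("pipeline stage %r failed", stage)
        summary["failed_stage"] = stage
        if outdir:
            (outdir / "summary.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True, default=str)
            )
        raise
    if outdir:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
    return summary
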