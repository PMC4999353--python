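"""Regional dose rate (RDR): windowed maximum dose increments per voxel.

During a long delivery a target voxel accrues dose in bursts separated
by idle stretches while other regions are treated.  The RDR at window
``t`` is, per voxel, the largest cumulative-dose increment observed in
any ``t``-minute span of the delivery:

    RDR_t(v) = max_a [ D(v, a) - D(v, a - t) ],   D(v, a < 0) := 0

with ``D`` the per-voxel cumulative dose sampled every minute.  The
boundary convention means a window overlapping the start of treatment
counts dose from zero, so "receives the prescription within t minutes"
is read literally.  RDR coverage at a threshold is the fraction of
target voxels whose RDR reaches it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delivery import DeliveryTimeline
from .phantom import StructureSet

__all__ = [
    "DoseTimeSeries",
    "RDRMap",
    "cumulative_series",
    "compute_rdr",
    "rdr_coverage",
]


@dataclass
class DoseTimeSeries:
    """Per-voxel cumulative dose (Gy) on a 1-minute grid.

    ``D[v, a]`` is the dose voxel ``v`` has received by minute ``a``,
    for ``a = 0 .. ceil(EFTT)``; non-decreasing along ``a`` with
    ``D[:, 0] = 0``.
    """

    voxel_indices: np.ndarray  # (N, 3)
    minutes: np.ndarray  # (A,)
    D: np.ndarray  # (N, A)

    def __post_init__(self) -> None:
        if self.D.shape != (len(self.voxel_indices), len(self.minutes)):
            raise ValueError("cumulative matrix shape mismatch")

    @property
    def final_dose(self) -> np.ndarray:
        return self.D[:, -1]


@dataclass
class RDRMap:
    """Per-voxel RDR values (Gy) for one window length."""

    window_min: int
    voxel_indices: np.ndarray
    values: np.ndarray


def cumulative_series(
    timeline: DeliveryTimeline,
    ptv_dose_matrix: np.ndarray,
    voxel_indices: np.ndarray,
) -> DoseTimeSeries:
    """Integrate per-beam voxel doses along the delivery timeline.

    ``ptv_dose_matrix[v, j]`` is the total dose beam ``j`` (column order
    = timeline event order) gives voxel ``v``.  Dose accrues linearly
    over each beam-on interval and is constant during overheads; the
    1-minute samples use exact fractional-interval accounting, so the
    last column equals the static plan dose at those voxels.
    """
    M = np.asarray(ptv_dose_matrix, dtype=np.float64)
    if M.shape[1] != len(timeline.events):
        raise ValueError(
            f"dose matrix has {M.shape[1]} beams but timeline has "
            f"{len(timeline.events)} events"
        )
    eftt = timeline.eftt_min
    minutes = np.arange(int(np.ceil(eftt - 1e-9)) + 1, dtype=float)
    iv = timeline.beam_on_intervals() if timeline.events else np.zeros((0, 2))
    on0, on1 = iv[:, 0], iv[:, 1]
    span = on1 - on0
    a = minutes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (a - on0[:, None]) / span[:, None]
    frac = np.where(span[:, None] > 0, frac, (a >= on0[:, None]).astype(float))
    frac = np.clip(frac, 0.0, 1.0)
    D = M @ frac
    np.maximum.accumulate(D, axis=1, out=D)  # guard monotonicity vs roundoff
    return DoseTimeSeries(voxel_indices=np.asarray(voxel_indices), minutes=minutes, D=D)


def compute_rdr(s: DoseTimeSeries, t_min: int) -> RDRMap:
    """Sliding-window maximum dose increment for a ``t_min``-minute window."""
    t = int(t_min)
    if t <= 0:
        raise ValueError(f"window must be >= 1 minute, got {t_min}")
    A = s.D.shape[1]
    if t > A - 1:
        t = A - 1 if A > 1 else 1
    lagged = np.zeros_like(s.D)
    if t < A:
        lagged[:, t:] = s.D[:, :-t] if t > 0 else s.D
    values = (s.D - lagged).max(axis=1)
    return RDRMap(window_min=int(t_min), voxel_indices=s.voxel_indices, values=values)


def rdr_coverage(
    m: RDRMap,
    threshold_gy: float,
    structures: StructureSet | None = None,
) -> dict[str, float] | float:
    """Fraction of voxels with RDR >= threshold.

    With a structure set, reports per-target (RPTV / LPTV) and combined
    fractions keyed by label; otherwise returns the combined fraction.
    """
    if threshold_gy <= 0:
        raise ValueError("threshold must be positive")
    if len(m.values) == 0:
        raise ValueError("RDR map has no voxels")
    hit = m.values >= threshold_gy
    if structures is None:
        return float(hit.mean())
    out: dict[str, float] = {}
    for label, mask in structures.ptvs().items():
        member = mask.voxels[
            m.voxel_indices[:, 0], m.voxel_indices[:, 1], m.voxel_indices[:, 2]
        ]
        if not member.any():
            raise ValueError(f"no RDR voxels inside {label}")
        out[label] = float(hit[member].mean())
    out["combined"] = float(hit.mean())
    return out
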