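"""Independent geometric oracles for the test suite.

The fast paths in the package traverse rays by boundary-plane crossing;
these oracles instead test every voxel of a structure against the ray
with an axis-aligned slab intersection, which is exact and shares no
code or algorithm with the implementation.
"""

import numpy as np


def slab_first_entry(grid, voxels, src, direction, t_max=None):
    """Earliest ray parameter (mm) at which the ray enters any set voxel,
    or None.  Exhaustive per-voxel ray-box test."""
    idx = np.argwhere(voxels)
    if len(idx) == 0:
        return None
    c = grid.voxel_centers(idx)
    h = np.asarray(grid.spacing_mm) / 2.0
    src = np.asarray(src, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    t0 = np.full(len(c), -np.inf)
    t1 = np.full(len(c), np.inf)
    for ax in range(3):
        lo = c[:, ax] - h[ax] - src[ax]
        hi = c[:, ax] + h[ax] - src[ax]
        if d[ax] == 0.0:
            outside = (lo > 0) | (hi < 0)
            t0[outside] = np.inf
        else:
            ta, tb = lo / d[ax], hi / d[ax]
            t0 = np.maximum(t0, np.minimum(ta, tb))
            t1 = np.minimum(t1, np.maximum(ta, tb))
    t0 = np.maximum(t0, 0.0)
    hit = t1 > t0
    if t_max is not None:
        hit &= t0 < t_max
    if not hit.any():
        return None
    return float(t0[hit].min())


def slab_entry_order(grid, masks, src, direction):
    """(label, depth) list ordered by first-entry depth, via the slab test."""
    entries = []
    for lab, m in masks.items():
        t = slab_first_entry(grid, m.voxels, src, direction)
        if t is not None:
            entries.append((lab, t))
    entries.sort(key=lambda e: e[1])
    return entries
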