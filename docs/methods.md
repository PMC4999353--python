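# Methods and design notes

This note documents the models behind `afplan`, the defaults and why
they were chosen, the numerical choices, and what the synthetic
phantoms can and cannot say about real patients.

## The clinical problem being simulated

Pulmonary-vein isolation for paroxysmal AF requires a closed
transmural lesion around the PV antra.  Done with a robotic
radiosurgery system, the prescription used here is 25 Gy in a single
fraction to at least 99 % of both planning target volumes (right and
left PV pairs), with hard limits on the esophagus, bronchial tree and
left coronary artery.  Three delivery-level questions drive the
package: (1) is the prescription achievable given the organ-at-risk
geometry, (2) does the *rate* at which each voxel accumulates dose
stay high enough to outrun early cellular repair during deliveries
that take an hour, and (3) how badly does differential motion degrade
coverage when the beams track a septal surrogate rather than the
lesions themselves.

## Phantom

The anatomy is analytic: an ellipsoidal left atrium (semi-axes
25 × 19 × 23 mm, population-typical, config-exposed) with four PV
cylinders (radius 8.5 mm), inside an ellipsoidal heart and an
elliptical-cylinder body, in an LPS-like frame (+x left, +y posterior,
+z superior) on a 2 mm isotropic 128³ grid (1 mm available through the
config at ~8× memory/time).  Lesions are built per PV *pair*: an
annular shell wide enough to encircle both ostia of the pair, with
width drawn uniformly from 4–6 mm along the veins and transmural depth
from 2–4 mm — the wide-antral circumferential pattern used clinically.
PTVs are exact Euclidean 3 mm dilations (world units, so anisotropic
grids are handled); with these defaults the combined PTV lands at
20–23 cc, inside the 17.0–49.1 cc range reported for clinical AF
plans.  A grid too coarse to represent the sampled lesion depth is
rejected rather than silently under-resolved.

The esophagus is a vertical 7 mm-radius tube placed by location class
(posterior to the right inferior PV, central near right, central away,
central near left, posterior to the left inferior PV), sampled with
the observed population frequencies (10.5/9.0/19.6/19.6/41.3 %).
"Near" classes solve the tube position so it abuts the PTV without
overlapping (the clinically unfavorable, often unplannable case);
"central-away" keeps more than 10 mm of clearance from both PTVs.  The
placement is solved against the realized masks, so the invariants hold
on any grid resolution.  PV variants (common left trunk, right middle
PV) are available behind a config flag.

The phantom is water-equivalent: no contrast, no heterogeneity.  Every
structure derives deterministically from one seed.

## Dose model

Each beam is a divergent cone from a source node at SAD = 800 mm:

    dose/MU = k0 · (SAD/d)² · exp(−μ·depth) · profile(r, s)

with μ = 0.004 mm⁻¹, a flat core out to 80 % of the (depth-scaled)
field radius, a Gaussian penumbra with σ = 2.5 mm, and k0 calibrated so
1 MU gives 1 cGy on axis at 15 mm depth.  Depth is measured from the
body-entry point of the central axis (exact plane-crossing traversal).
There is no build-up region, scatter, or heterogeneity correction; the
kernel is plausible 6 MV-like behavior, not a claim of absolute
dosimetry.  What the downstream analyses rely on — exact MU linearity,
beam superposition, monotone depth falloff, sharp lateral penumbra —
holds by construction and is tested.

Collimators default to {20, 25} mm: the PTV is a thin annulus
(~10–12 mm tube cross-section), and wider fields mostly irradiate the
lumen and the structures behind the target.

## MU optimization

Candidates: 100 quasi-uniform (Fibonacci) nodes on the anterior source
hemisphere, one beam per node per target aimed at a seeded-random PTV
voxel.  The optimizer is iteratively reweighted nonnegative least
squares, solved by accelerated projected gradient (FISTA, 400
iterations, Lipschitz constant by power iteration — deterministic and
warm-startable).  Six reweighting rounds: target voxels below the
prescription get their row weight boosted (capped at 30×); penalty
points above their guide dose enter one-sidedly with weight
proportional to the violation.  Penalty points are all organ-at-risk
voxels within 80 mm of the targets (guides at 85 % of each organ's
tightest limit) plus a 4–25 mm normal-tissue shell around the PTVs
(guide 0.9 × prescription) against hot spots.  After the fit, beams
under 1 % of the maximum MU are pruned and the survivors re-fit, then a
global rescale pins the coverage quantile of the PTV at the
prescription (0.2 % headroom so that grid-level re-evaluation cannot
drop below the coverage rule).  Feasibility is reported, never forced:
the plan carries a structured constraint report, and unfavorable
esophagus classes come back flagged infeasible.

In **divided-node-set mode** (right target from anterior + right-
lateral nodes, left target from left-lateral + anterior, delivered
sequentially) both the fit and the rescale are *phase-aware*: each
lesion is prescribed from its own node-set's beams, and cross-phase
dose rides on top.  With sequential per-lesion delivery this is the
defensible prescription convention — it guarantees each covered voxel
reaches the dose within its own delivery phase, which is the entire
point of dividing the node set — and it is what separate per-lesion
planning would do.

Grade-1 thresholds written with "<" are strict (equality fails);
grade-3 thresholds are hard planning limits with "≤".  Limits for
organs without a mask (major vessels) are reported "not evaluated".

## Delivery model and RDR

The treatment-time formula and its per-beam allocation are in the
`delivery` module docstring; the machine constants it needs (dose
output, images per beam) are not published for the reference plans, so
they default to 800 MU/min and 1 and are config-exposed.  With
1000 MU/min and 2 images per beam the formula lands within ±15 % of
all eighteen published (nodes, beams, MU → EFTT) rows used as a
calibration check, and the default phantom plan's EFTT falls inside
the published 50–87 min range.  The formula term "beams / images per
beam / 10" is implemented literally (dividing); whether more images
per beam should increase imaging time is ambiguous as printed.

Re-sorting groups beams into four contiguous phases by which target
the central axis meets first (right-only, right-then-left,
left-then-right, left-only; beams missing both go last), with
nearest-neighbor node traversal inside each phase.  Since nodes
contributing to several phases are revisited at 0.25 min per visit,
re-sorting can only lengthen the treatment — dose is permutation-
invariant and tested to 1e-12.

Cumulative per-voxel dose is sampled on a 1-minute grid with exact
fractional accounting of each beam-on interval (dose accrues linearly
while the beam is on).  RDR_t(v) = max_a [D(v,a) − D(v,a−t)] with
D(a<0) = 0, computed as a sliding window and verified against an O(n²)
brute force; the boundary convention means a window covering the start
counts dose from zero (closed-interval difference; the printed source
does not specify open vs closed ends).  RDR is evaluated at PTV voxels
by default; coverage is reported per target and combined.

## 4D motion model

Displacement fields live on the reference grid (end-expiration).
Respiratory mode has two phases weighted 0.6/0.4
(expiration-dominant); the inspiration field is the septum amplitude
vector (medians 12.8 mm I/S, 13.3 mm A/P, 4.1 mm L/R; vector norm
18.9 mm, against a published 3D median of 19.8 mm) scaled by a
smoothstep profile from 1 at the septum down to the differential
factor (default 0.6, unquantified in the source and config-exposed) at
the left PVs.  Cardiac mode is an n-phase (default 8) sinusoidal
displacement along the septum→LA axis with a Gaussian spatial envelope
(10 mm at the septum, λ = 25 mm), so motion at the PV antra is small.

Accumulation exploits the water-equivalent body: under surrogate
tracking the whole dose cloud translates rigidly with the surrogate
shift Δ_p, so

    D_acc(x) = Σ_p w_p · D_static(x + u_p(x) − Δ_p)

by trilinear pull-back with the forward field — no numerical field
inversion is needed, and the zero-motion and perfect-tracking
identities are exact at grid points.  A Jacobian fold check reports
voxels where det(I + ∇u) ≤ 0.  Cardiac accumulation runs *untracked*
(Δ_p = 0): the tracking loop follows the respiratory surrogate, not
the heartbeat, which is exactly why uncompensated cardiac motion near
the septum can dent coverage of the right target.

The 4D optimizer reuses the MU machinery with per-beam doses evaluated
at the displaced sample positions of every phase and phase-weight
summed, so the coverage rescale pins the *accumulated* dose at the
prescription.  With zero motion it reduces to the static optimizer.

## What the phantom studies do and do not show

Passing tests demonstrate that the algorithms are correct and that the
qualitative clinical findings emerge from the modeled geometry:
coverage is plannable in the favorable esophagus class and flagged
otherwise; standard path ordering gives poor 45-minute RDR coverage
while re-sorting and node-set division lift it above 80 %; septal
surrogate tracking loses more left- than right-target coverage and 4D
optimization recovers it; probe blocking costs well under a percentage
point of coverage.  They do not validate absolute dosimetry, real
patient anatomy variation, deformable registration of real 4D-CTs, or
the dose-response question of whether 25 Gy suffices — all outside
scope.  The delivered-dose figures of merit use problem sizes chosen
for a desk-scale study (2 mm grid, 100 nodes, one candidate beam per
node per target); finer grids and denser candidate sets are config
switches, not code changes.

## I/O conventions

Volumes are NIfTI (nibabel) carrying the grid affine; beam lists,
timelines, DVH and RDR tables are CSV; reports and the structure
manifest are JSON; run configuration is YAML/JSON validated by
pydantic and echoed (minus output paths) into every summary so results
are self-describing and byte-reproducible per seed.  DICOM-RT is not
supported.
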