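# Methods

`gastrusim` simulates the pre-gastrulation chick epiblast as a bounded
planar cell-centre model.  This note records the model, its parameters,
the numerical choices, and what the synthetic test conditions do and do
not establish.

## Model overview

The embryo is a disc of ~1000 spherical cells (radius 5 μm) in a plane,
encircled by a ring of marginal-zone (MZ) pseudo-cells, over a schematic
hypoblast/endoblast lower layer.  Time advances in 10-minute ticks for 72
ticks (~12 h, roughly stage XI to stage 3+); space is continuous, in μm.
Each tick executes a fixed phase order: lower-layer advance, MZ
displacement and resampling, neighbour-structure rebuild, synchronous
stochastic state conversions (Nodal → Wnt-PCP → EMT initiation), vertical
EMT sub-steps, cell cycling, 1000 interleaved equilibration/intercalation
sub-iterations, and the orientation-consensus update.

### Stochastic state machinery

Every hazard is a generalized logistic `p(x) = p_min + (p_max −
p_min)/(1 + e^{−(x−m)/s})` in probability per hour, converted to
per-tick probabilities by survival-consistent compounding `1 − (1 −
p_hr)^{dt}`.  Neighbour influence enters through the effective neighbour
equivalents

    N_eff = k_self·[self] + k_nn·(#effector near-neighbours)
            + k_n·Σ_{local, d<d_max} e^{−d²/(2σ_d²)},

with near-neighbours read from the pseudo-Voronoi adjacency and local
neighbours from centre-to-centre distances (untethered-EMT cells count as
local effectors only).  Receivers under the hypoblast (which secretes the
Nodal antagonist Cerberus) use a weakened coefficient set (k_nn 1.0 → 0.6,
k_n 1.0 → 0.0, and for the EMT table k_self 1.0 → 0.6).

Hazard tables (per hour):

| process | p_min | p_max | m | s |
|---|---|---|---|---|
| EMT initiation (vs N_eff) | 0.02 | 0.999 | 8.0 | 1.0 |
| Nodal conversion (vs N_eff) | 0.0 | 0.999 | 2.0 | 0.25 |
| Wnt-PCP conversion (vs N_eff; requires Nodal⁺) | 0.0 | 0.999 | 1.0 | 0.25 |
| direction change, ascending (vs z) | 0.8 | 0.0 | −5.0 | 1.0 |
| direction change, descending (vs z) | 0.0 | 0.4 | −5.0 | 1.0 |
| reversion t-emt → epithelium (vs z) | 0.30 | 0.90 | −5.0 | 1.5 |
| untethering (vs depth; below BM only) | 0.0 | 0.999 | −12.5 | 1.0 |

The untethering table is printed with a logistic that would *decrease*
with depth, contradicting the accompanying text; we follow the text and
evaluate the curve on the depth-mirrored argument `2m − z`, so the hazard
rises from 0 at the basement membrane (z = −2r) to 0.999 at depth.
Reversion is prohibited for untethered cells, cells fully below the BM,
and whenever the local Nodal effect is ≥ 1.0 (the effect a disinhibited
Nodal-positive cell exerts on itself) — the mechanism that locks
ingression on at the streak.

### Mechanics

Cell centring is Lloyd's algorithm on the pseudo-Voronoi tessellation
(straight bisector polygons, radius differences ignored; MZ pseudo-cells
are boundary generators without regions of their own).  Oriented
intercalation (OI) gives each Wnt-PCP-positive cell, for every
Wnt-PCP-positive near-neighbour, a displacement of magnitude |sin θ| μm
per sub-iteration toward the line through the neighbour along the
orientation axis (θ = angle between the cell→neighbour direction and the
cell's own axis).  Axes are nematic; each tick they relax to a consensus
(own axis + sign-aligned neighbour mean, iterated to < 0.5° change or 200
sweeps), anchored by MZ reference axes perpendicular to the ring.  The
|sin θ| magnitude is the model's printed displacement scale; with 1000
sub-iterations per tick, intercalation is fast compared with state
conversion, which is what keeps the forming streak narrow.

The MZ ring moves once per tick by the sum of a curvature vector
(k_curv·κ toward the local curvature centre, κ from the three-point
circumcircle), an outward density push (k_dens Σ e^{−d²/(2·15²)} over
epiblast cells within 55 μm), and an area-correction term.  The target
area follows the logarithmic density-rise schedule with a running
maximum; the correction controller is `clamp(gain·(A_target −
A_ring)/perimeter, ±2 μm)` — a uniform normal displacement δ changes the
enclosed area by ≈ perimeter·δ, so unit gain closes the loop in about one
step.  The clamp must exceed the curvature pull k_curv/R, which is why it
is larger than a naive sub-micron bound; at the default embryo size both
work, but small test embryos need the wider clamp.

### Lower layer and initial conditions

The hypoblast is a disc polygon covering (and growing with) the MZ ring.
From tick 30 an endoblast band sweeps anteriorly from the posterior
margin at 6% of the disc diameter per tick, uncovering the
streak-forming cohort within ~5 ticks, and stops at 30% of the disc
radius behind the centre (`endoblast_stop_y_frac = −0.3`).  The stop
position is a modelling choice (the source gives stages, not geometry):
sweeping the whole disc disinhibits Nodal everywhere and the posterior
epiblast converts wholesale, while a posterior-sector band reproduces the
observed discrete streak.

The initial epiblast is a hexagonally packed disc (packing fraction
0.9069, so 1000 cells of radius 5 μm give a disc radius of ~166 μm) with
0.3 μm positional jitter.  The SAE / Koller's-sickle cohort is the 95
cells nearest the posterior margin within an ±85° wedge about the
posterior pole — a thin two-row sickle.  A deeper, narrower crescent
(e.g. ±60°, three rows) converts its anterior boundary noticeably faster
pre-disinhibition (three Nodal⁺ contacts give 0.31/hr even under
inhibition), which blurs the cohort; the thin arc matches the depicted
sickle and keeps the pre-streak cohort stable.  SAE axes start radial
(perpendicular to the MZ), the orientation the consensus anchor itself
enforces.

Cycle lengths are normal with mean 6 h and 10% CV, truncated at ±3 SD;
initial phases are uniform.  Daughters are placed ±r/2 along a uniformly
random planar axis at half parental volume (radius ×2^{−1/3}),
regrowing linearly over 1 h; they inherit Nodal/Wnt-PCP states and the
OI axis.  Tethered-EMT and deeper cells do not divide.

Vertical motion uses 2.5 μm/tick; untethered cells convert to terminal
mesenchyme at z = −25 μm and lose all signalling positivity.
Post-ingression mesenchyme behaviour is not modelled.

## Numerical choices

* **Tessellation**: `scipy.spatial.Voronoi` per sub-iteration; region
  centroids are accumulated ridge-wise (each region is convex and
  contains its generator, so generator/ridge-vertex triangles partition
  it), avoiding per-region Python loops.  Exactly coincident generators
  are jittered apart by 1 nm with a warning.
* **Containment**: after each tick's relaxation any cell outside the MZ
  polygon is pulled back along the ray to the ring centroid.
* **Synchronous conversions**: all Nodal/Wnt-PCP/EMT hazards are
  evaluated against the start-of-tick state and applied together, so
  outcomes are independent of cell iteration order.  One global RNG
  stream is consumed in a fixed order; runs are bit-reproducible given
  (scenario, seed).
* **OI micro-substeps** (`oi_substeps`): reduced-size test runs rebuild
  the tessellation fewer times per tick (e.g. 200 instead of 1000) and
  apply several OI micro-updates per rebuild so that the total number of
  OI updates per tick stays at the default budget (200 × 5 = 1000).
  Because fewer Lloyd recentrings interleave the OI updates, this runs
  convergent extension somewhat hot relative to the strict 1000 × 1
  schedule (the block benchmark converges faster at equal budget); it is
  a numerical acceleration for desk-scale runs, not a new mechanism, and
  full-size runs use the strict schedule.
* **Degenerate inputs**: unbounded or zero-area Voronoi regions leave the
  cell in place for that sub-iteration; consensus keeps the previous axis
  when the neighbour sum vanishes (antiparallel degeneracy); collinear
  ring triples have zero curvature with the inward disc normal.

## Test conditions (what the synthetic runs show)

The test suite exercises the model at reduced size — typically 250–300
cells with proportionally scaled SAE cohorts and 200×5 (or 100×10)
rebuild/substep relaxation — so that whole-suite runtime stays in
minutes.  Because the signalling length scales (d_max = 40 μm, σ_d = 10
μm) are absolute, smaller discs have relatively *stronger* neighbour
coupling: conversion fronts occupy a larger fraction of the tissue and
phenotype contrasts are compressed compared with the full-size embryo.
The qualitative phenotypes (narrow posterior streak, ingression
concentrated in the streak, bilateral counter-rotation, PCP-block and
graft responses) are robust at that scale; quantitative morphometrics at
full size are expected to be cleaner, not worse.  The generator emulates
none of: 3D columnar architecture, real-embryo dimensions (3–5 mm),
molecular pathway detail, middle-layer migration, or oriented division —
conclusions about those features cannot be drawn from passing tests.

## Known limitations

* The nematic consensus has no bilateral-symmetry constraint, so the
  streak axis can tilt or drift off the midline by tens of μm in a
  minority of seeds, more so at small tissue size.
* The epiblast is consumed faster (relative to its size) at reduced scale
  because conversion-front width is set by absolute distances.
* The MZ ring never shrinks (the area schedule's running maximum), so
  heavy late ingression lowers planar density rather than contracting the
  embryo.
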