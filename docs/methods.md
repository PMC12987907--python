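# Methods

`canalplan` evaluates whether three keyhole drill tunnels — one to each
semicircular canal (SCC) of the inner ear — can be placed from a small
retroauricular region on the mastoid surface without endangering the
structures between the skin and the labyrinth.  This note documents the
model, its parameters, the synthetic anatomy used for testing, and the
numerical choices.

## The planning model

A candidate trajectory is a straight segment from an **entry point** on the
outer mastoid surface to a **fenestration site** on a canal.  Three
quantities decide its fate:

1. **Safety margin.** A stepped drill (tip radius 0.5 mm, widening to
   0.6 mm at 4 mm and 1.25 mm at 14 mm behind the tip) is swept along the
   path.  At every sample the clearance to an obstacle is the interpolated
   signed distance to that obstacle's surface minus the local drill
   radius; the safety margin is the minimum clearance over the path and
   over all obstacles.  Obstacles are the two non-target canals, facial
   nerve, chorda tympani, lateral skull base, sigmoid sinus and external
   auditory canal; the target canal is excluded because the drill must
   enter it.  Negative margins (collisions) are reported as-is, never
   clipped.
2. **Canal entry angle.** The angle between the drill direction and the
   ampulla-directed tangent of the canal centreline at the fenestration
   site; 0° is a perfectly tangential anterograde approach, above 80° the
   inserted electrode risks turning retrograde.
3. **Accessibility.** An entry point is *accessible* for a canal iff the
   margin strictly exceeds the threshold (0.5 / 1 / 2 mm are reported;
   1 mm is the working threshold) and the angle is strictly below 80°.
   A canal's accessibility is the percentage of accessible entry points.

### Drill targets

Canal centrelines are recovered by voxelizing the canal surface on a
0.1 mm grid, 3-D thinning (Lee's method), ordering the skeleton voxels
along their longest geodesic path, and fitting a cubic smoothing spline
whose smoothing factor is relaxed until the curve stays within 0.1 mm of
the skeleton.  Thinning erodes the curve ends near the canal end caps, so
both ends are extended along their tangents until they meet the canal
surface; without this the arc length is underestimated by roughly one
lumen radius per end.  The **electrode target** is the centreline point
closest to the annotated nerve-stimulation target; the **fenestration
site** sits a configurable arc-length offset (default 2 mm) from it in
the direction away from the ampulla, the ampullary end being the
centreline end nearer the nerve target.

### Exposed-area model

To justify an ideal entry angle, the package models the canal as a
straight cylindrical lumen (diameter 1.1 mm, the midpoint of the 1.0–1.2
mm range of human canals) and the drill as a cylinder with a
hemispherical 0.5 mm tip whose tip centre stops on the canal axis.  The
canal-wall area inside the swept drill volume is integrated numerically
on the developed cylinder surface, doubling the sampling until the value
changes by less than 1%.  The area grows steeply below ~30°, which is the
quantitative basis for the 30° ideal angle used by the optimizer.

### Mutual optimization

All three electrodes branch from one implant lead, so the three entry
points must fit a single cortical mastoidectomy.  The optimizer searches
the accessible entry points (the same sampled set for all canals) for one
triple — one entry per canal — with all pairwise distances strictly below
12.5 mm, minimizing `sum_i (alpha_i − 30°)²`.  The search is exact: canals
are processed fewest-candidates-first, candidates are sorted by cost, and
branches are pruned with additive lower bounds, so the returned objective
equals the exhaustive minimum.  Ties are broken by smaller maximum
pairwise distance, then lexicographic entry indices, making the result
deterministic.  A case is feasible when the minimal enclosing circle of
the three chosen entries fits the 15 mm mastoidectomy; the 12.5 mm
pairwise bound already guarantees this (worst case, an equilateral
triangle, has enclosing diameter 2·12.5/√3 ≈ 14.4 mm), which is how the
two printed constraints are reconciled.

## Geometry engine

Distance queries drive the entire analysis, so they are implemented as
first-class primitives:

* **Exact signed distance.** Closest-point queries use a k-d tree over
  triangle centroids with an escalation certificate (a point's result is
  accepted only when no unexamined triangle could be closer), so node
  values are exact to machine precision, not approximate.  Grids are
  evaluated per 8³-node block with a shared, provably sufficient
  candidate set and an early-exit scan bound.  The inside/outside sign
  uses angle-weighted pseudonormals, exact for watertight meshes; open
  surfaces (skull base, sigmoid shape) yield unsigned distances.  Fields
  are sampled on a regular grid (0.125 mm clinically; see problem sizes
  below) with trilinear interpolation off-node and a hard error outside
  the grid — no silent extrapolation.
* **Ray casting** is a chunked Möller–Trumbore intersection; it backs the
  entry-region projection, sigmoid reconstruction and parity-based
  containment tests.
* **Alpha shape.** The sigmoid sinus is reconstructed by casting 256
  uniformly distributed rays (Fibonacci sphere) from points every 0.5 mm
  along the annotated sinus centreline and taking the alpha shape of the
  hits.  The alpha complex keeps Delaunay tetrahedra with circumradius
  below 1/alpha; alpha = 0.1 (i.e. 10 mm) follows the convention of the
  common `alphashape` package, since the parameter's convention is
  otherwise ambiguous.  Centreline samples within half a sample spacing
  of the annotation ends are dropped: annotated centrelines commonly end
  at the segmentation boundary, and rays from boundary points escape the
  sinus and contaminate the point cloud.

### Derived surfaces

* **ROI crop**: a vertical triangular prism (equilateral footprint,
  60 mm circumradius, centred 10 mm posterior to the inner-ear centre);
  faces are kept when all vertices satisfy the three half-plane
  inequalities.  The source material gives no prism dimensions; these
  cover the full analysis volume on every tested anatomy.
* **Outer surface**: the convex hull is remeshed to uniform vertex
  spacing (subdivision targeted at twice the requested face area, so the
  median face lands near the target) and iteratively relaxed (uniform
  Laplacian) and projected to the nearest point of the original surface.
  The iteration stops when the maximum per-iteration vertex displacement
  falls below max(0.01 mm, 3% of the vertex spacing); the relaxation
  weight is damped from iteration 15 on so tangential sliding across flat
  regions settles.  Because the wrap approaches from outside, interior
  cavity walls (air cells, the sinus channel) are never reached.
* **Lateral skull base**: the connected face component seeded from the
  face directly superior to the inner-ear centre, clipped to a box from
  3 mm below the superior hit upward.  Growth is restricted to
  upward-facing faces (normal z > 0.1) so the component cannot leak down
  vertical walls sharing the box; the superior ray skips downward-facing
  hits (plate undersides).  The sigmoid surface is subtracted by removing
  faces whose centroids lie inside it (containment-based subtraction; an
  exact mesh boolean is deliberately out of scope).
* **Entry region**: a 30 × 30 mm sagittal square, anterior edge at the
  ear-canal centre, vertically centred, plus a 10 × 10 mm superoanterior
  extension; total planar area 1000 mm².  Sampling is a stratified
  jittered grid (deterministic per seed, jitter 25% of the cell) bisected
  to the exact requested count (5000 clinically), projected along the
  lateral axis onto the outer surface; a run errors out when more than 1%
  of samples miss.

## Synthetic anatomy

No imaging cohort ships with the package, so a seeded generator builds
cases with the geometric structure the analysis assumes, in a right-ear
frame (origin at the inner-ear centre, +x lateral, +y anterior,
+z superior, mm):

* canals as torus-arc tubes (major radius 3.2 mm, arc 246°, lumen
  diameter 1.1 mm) with an ellipsoid-like ampullary swelling; canonical
  plane orientations (lateral ≈ tilted axial, superior ≈ near-sagittal,
  posterior ≈ vertical facing anterolaterally); the in-plane orientation
  is chosen so each canal loops posteriorly away from its ampulla, as
  real canals do — this fixes the sign of the ampulla-directed tangent
  that entry angles are measured against;
* facial nerve (radius 0.6 mm) descending through the mastoid with the
  chorda tympani (0.25 mm) branching anteriorly; a cylindrical ear canal
  (radius 3.5 mm) along the lateral axis;
* a bone block whose superior face slopes from 16 mm laterally down to
  9 mm medially — the medial roof sits just above the superior canal
  apex, which is what makes tangential superior-canal approaches scrape
  the skull base, as they do in patients;
* a sigmoid-sinus channel (radius 4 mm) grooving the posterior mastoid,
  extending beyond its annotated centreline as the real sinus does, and
  optional spherical air cells to exercise cavity-free outer-surface
  extraction;
* stimulation targets on each canal axis at the ampullary end, and a
  cochlear-implant reference trajectory entering anteroinferiorly.

Cohort variation is uniform: ±10% sizes, ±10° canal-plane jitter,
sigmoid position jitter (±3 mm anteroposterior, ±2 mm vertical, ±1 mm
lateral — anisotropic so the channel stays interior to the block), and a
random left/right mix.  Left ears are exact sagittal mirrors, which
makes pipeline mirror-invariance exactly testable.

What the generator does **not** emulate: true morphometric distributions
of the human temporal bone, the common crus, petrous air-cell networks,
or imaging/segmentation noise.  Passing tests therefore demonstrate the
correctness and invariances of the *method* — not clinical accessibility
statistics, which depend on real anatomy.

## Problem sizes

The clinical defaults (5000 entry points, 0.125 mm fields and path
sampling, 0.1 mm² outer faces, 256 sigmoid rays per sample) are what the
configuration ships with.  Tests and the acceptance script use the
`PipelineConfig.coarse` preset — 400 entry points, 0.5 mm fields,
0.25 mm path sampling, 1 mm² outer faces, 96 rays — which leaves every
threshold, drill dimension and angular constant untouched and completes a
case in well under a minute on one core.  Accessibility percentages move
by a few points between the two presets; orderings and feasibility flags
have been stable in all runs.

## Known limitations

* Straight trajectories only; no robot kinematics, drill deflection or
  electrode mechanics.
* The cochlea is not part of the obstacle set, mirroring the clearance
  analysis this package implements; vestibular trajectories pass
  posterior to it.
* Containment-based subtraction leaves the sigmoid opening in the skull
  base un-stitched (the surfaces are used only as distance obstacles).
* Accessibility statistics on synthetic cohorts are not predictions for
  patients; they exercise the machinery.
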