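# canalplan

Feasibility analysis of **robotic keyhole access to the semicircular
canals** for vestibular implantation.

Vestibular implants restore balance sensation by stimulating the
ampullary nerves of the three semicircular canals (SCCs).  Placing the
electrodes requires opening each canal precisely — a hard ask through a
conventional mastoidectomy, because the canals are buried in dense
labyrinthine bone next to the facial nerve, sigmoid sinus and skull
base.  Image-guided robotic drilling offers an alternative: three narrow
tunnels from the mastoid surface straight to the canals.  `canalplan`
answers the planning question: *from where on the mastoid can each canal
be reached safely and at a usable angle, and can all three tunnels share
one small mastoidectomy?*

It is a library for surgical-planning researchers, with a thin CLI; it
works on segmented surface models (STL/PLY, mm) and ships a seeded
synthetic temporal-bone generator so every stage is testable without
patient data.

## The model

For an entry point $e$ on the outer mastoid surface and a fenestration
site $f$ on a canal centreline, the trajectory $e \to f$ is evaluated by:

* **safety margin** $\;m = \min_{s,\,o}\big[d_o(x(s)) - r(\ell - s)\big]$ —
  the minimum over path samples $x(s)$ and obstacles $o$ of the distance
  to the obstacle surface minus the stepped drill radius
  ($r = 0.5$ mm at the tip, $0.6$ mm from 4 mm, $1.25$ mm from 14 mm
  behind the tip).  Obstacles: the two other canals, facial nerve, chorda
  tympani, lateral skull base, sigmoid sinus, external auditory canal.
* **SCC entry angle** $\alpha$ — between the drill direction and the
  ampulla-directed centreline tangent at $f$ (0° = tangential
  anterograde).
* **accessibility** — a trajectory is accessible iff $m > 1$ mm and
  $\alpha < 80°$; a canal's accessibility is the percentage of accessible
  entry points among 5000 evenly spaced samples of a 30 × 30 mm
  retroauricular region (plus a 10 × 10 mm superoanterior extension).

An idealized exposed-lumen-area model (spherical-tipped drill entering a
1.1 mm cylindrical lumen) sets the **ideal angle at 30°**; the three
trajectories are then jointly selected by minimizing
$\sum_i (\alpha_i - 30°)^2$ subject to $m_i > 1$ mm, $\alpha_i < 80°$ and
pairwise entry distances $< 12.5$ mm, which guarantees all three entries
fit a **15 mm mastoidectomy** circle.  The discrete search is exact
(prunes to the exhaustive optimum, deterministic tie-breaking).

Distance evaluations use signed distance fields sampled on a regular
grid (node values exact to machine precision, trilinear off-node); canal
centrelines come from 0.1 mm voxelization, 3-D thinning (Lee), and
smoothing-spline fitting.  See `docs/methods.md` for the full account.

## Worked example

`examples/03_plan_single_case.py` generates a synthetic right ear and
plans all three trajectories at desk-scale problem sizes:

```
accessibility (% of entry points with margin > threshold, angle < 80 deg)
  superior  @0.5mm  40.8%  @1mm  30.0%  @2mm   0.0%  | lowest accessible entry angle 18.3 deg
  lateral   @0.5mm  57.8%  @1mm  56.0%  @2mm   0.0%  | lowest accessible entry angle 23.8 deg
  posterior @0.5mm  62.0%  @1mm  54.2%  @2mm  33.5%  | lowest accessible entry angle 1.5 deg

mutual plan feasible: True
  superior  entry angle  30.5 deg, margin 1.78 mm, drill length 22.6 mm
  lateral   entry angle  30.2 deg, margin 1.77 mm, drill length 25.6 mm
  posterior entry angle  30.4 deg, margin 2.22 mm, drill length 17.5 mm
  objective sum((angle-30)^2): 0.43 deg^2
  enclosing circle of the three entries: 11.2 mm
  (needs to fit the 15 mm mastoidectomy)
```

Reading: roughly half the retroauricular region reaches the lateral and
posterior canals with a 1 mm margin; raising the demanded margin to 2 mm
shrinks access (to zero for the superior and lateral canals on this
anatomy).  The joint optimization finds three entries within an 11.2 mm
circle, each entering its canal within half a degree of the 30° ideal.
The exposed-area curve behind that ideal (`examples/02_exposure_model.py`):

```
 angle (deg)  exposed area (mm^2)
          10                4.529
          30                1.836  <- ideal trade-off
          60                1.056
          90                0.919
```

A tangential 10° entry exposes five times the canal wall of a
right-angled one; 30° trades limited exposure against a still-straight
electrode path.

The other examples cover anatomy generation (`01`), cohort summaries
(`04`) and the fenestration-site sweep (`05`).  The same capabilities are
available from the shell:

```bash
canalplan simulate cohort/ --n 10 --seed 7
canalplan cohort cohort/ --outdir results/
canalplan sweep cohort/case_000 --canal superior
canalplan exposure --plot exposure.png
```

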