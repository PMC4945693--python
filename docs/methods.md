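# Methods

This note records the models implemented in `fetalkick`, the parameter
choices that matter, and the limits of what the synthetic, desk-scale
reimplementation can show.

## Synthetic kick sequences

The generator produces a planar extension kick inside an elliptical
uterus. Coordinates are uterus-centred, in mm, x along the major axis.
The cavity surface is the outer wall ellipse shrunk by the wall build-up
(0.6 mm membrane + 6.0 mm muscle). The ankle approaches the cavity
surface along the inward normal at the contact site with a cubic
ease-in-out profile, reaches it at the configured contact fraction of the
sequence (default 0.5), and then pushes the wall outward along the same
normal with a smooth ramp to the scenario's maximal deflection at the
last frame. The hip sits near-extension distance from the contact point,
offset 4 mm laterally from the push line so that the wall reaction
demands a net hip-flexion moment — the flexed-hip kick posture described
for kicks in utero, where restricted space forces the fetus to close the
torso-thigh angle while kicking. The knee is placed by two-link inverse
geometry, so femur and tibia lengths are conserved exactly at every
frame (the tests assert 1e-9 mm). Frame count is
`floor(duration / 0.303 s) + 1`.

Two generator choices exist purely to put the sequences in the regime the
tracking stage assumes, and are fixed:

* the pre-contact ankle speed is capped at 2 mm per frame (the tracker
  bounds inter-frame motion, mirroring the bounded "likely movement" any
  such tracker must assume);
* rendered structures have soft (sigmoid) edges, width 0.6 mm. Hard
  binary masks alias: sub-pixel motion flips whole pixels between frames
  and no correlation tracker can localize smoothly through that.

Rendering draws the wall band (intensity 0.45, bulged outward under the
foot by the current deflection with a Gaussian falloff), tapered bone
shafts (0.65; the intensity fades toward the epiphyses so joint
neighbourhoods are dominated by the joint markers), and Gaussian joint
blobs (amplitude 0.9, sigma 2.5 mm) — joints are the brightest local
structures, as they must be identifiable landmarks for seeding and
tracking. Gaussian blur (sigma 1.5 mm) and additive Gaussian noise
(5 % of the dynamic range) follow, both configurable per scenario;
rendering is bit-reproducible under a fixed seed.

What the synthetic data does **not** emulate: MRI contrast physics,
through-plane motion, the fetal torso and arms, maternal tissue, or
texture inside the wall and limb. Tracker success on these sequences
shows the algorithm is correct and robust at the stated noise, pixel
size and kick speeds — not that it would reach the same accuracy on
clinical scans.

## Joint tracking

Per frame, the hip is located first, then the knee, then the ankle. The
matching statistic is a centre-weighted (Gaussian-tapered, sigma = patch
half-width) zero-normalized cross-correlation, evaluated for every
template in a recency-weighted ensemble (geometric decay 0.8 per frame,
newest templates heaviest, at most 12 kept) and combined as the
weight-normalized average. Matching runs at two template scales
(half-widths 2 and 3 px, score maps blended 0.6/0.4); the small scale
limits the bias that neighbouring structures (notably the bright wall
next to the ankle) exert on the match, the larger one suppresses noise.
The peak is refined to sub-pixel accuracy by a three-point parabola, and
new templates are extracted at the sub-pixel position by bilinear
interpolation so they stay landmark-centred. Knee candidates are
restricted to the intersection of the search disc (radius 5 px for the
knee, which sweeps fastest; 3 px otherwise) with the annulus keeping the
hip-knee distance within +/-10 % of the running femur length (an
exponential moving average, rate 0.3, seeded from frame 0); the ankle is
constrained the same way against the tibia. Matches below correlation
0.3 raise a track-lost error; matches below 0.6 are kept as positions
but do not refresh the ensembles, so a single bad frame cannot corrupt
the templates. Ties resolve to the smallest row-major candidate.

Wall deflection: a frame is in contact when the tracked ankle is within
half a pixel of the cavity surface or beyond it; the deflection is the
Euclidean displacement of the ankle from its position at first contact,
maximized over the contact window. Summary statistics use the population
standard deviation (divisor n), the convention matching the reported
cohort dispersions.

Measured on three independent 20-seed blocks of cohort fixtures at the
default noise, 95.5-96.6 % of joint-frames localize within 1 px, and
noiseless sequences recover ground truth within 1 px at every frame.

## Uterine-wall finite elements

Geometry: half of the uterine ellipse (cut along the major axis), wall =
2 element layers of membrane + 6 of muscle, radially conforming bilinear
quads graded from 1 mm circumferential size at the contact site to 4 mm
far away. The foot is a round-ended cartilage probe (diameter 15 mm,
E = 1.1 MPa, nu = 0.49) meshed by transfinite interpolation, its tip arc
just clearing the faceted cavity surface (the probe is retracted by the
chord sagitta, a few micrometres, so the zero-displacement state is
force-free).

Contact sits at the arc midpoint of the half model — the minor-axis
apex — which is the point farthest from both cut boundaries (avoiding
edge effects) and the only location at which symmetry boundary
conditions are exactly consistent with a single probe load. The cuts
carry u_y = 0; the remaining rigid x-translation is removed by pinning
u_x on the contact meridian (x = 0), where symmetry demands it vanish, so
the ring remains free to ovalize. This matters physically: the local
curvature radius at the apex (a^2/b) differs strongly between fetuses
(76, 154 and 91 mm for A, B, C) and drives the per-fetus force ordering.

Elements: isoparametric bilinear plane-stress quads. The shear component
is integrated at the centroid in a per-element local frame (selective
reduced integration); the normal components use the 2x2 Gauss points.
Fully integrated bilinear quads lock severely on this thin curved wall —
at practical mesh sizes they overestimate the contact force by one to two
orders of magnitude and refuse to converge under refinement — while the
SRI element passes the patch test exactly, keeps all three rigid-body
modes and no spurious ones, reproduces the slender-cantilever oracle to
0.1 %, and converges the contact force to under 2 % between successive
wall meshes. Full integration remains available (`reduced_shear=False`).

Kinematics are finite-deformation (total-Lagrangian, Green-Lagrange
strain, St. Venant-Kirchhoff material): a ~7 mm deflection of a 6.6 mm
wall involves finite rotation and membrane stretching. Contact is
frictionless node-to-segment with penalty regularization: probe tip nodes
against the cavity-surface chain, node-averaged (continuous) master
normals, penalty stiffness 0.01 x the softest modulus x depth per mm of
penetration, and a C1-regularized activation ramp over 2 um. The much
stiffer penalty sometimes recommended (100x) makes the Newton iteration
chatter without converging; at the chosen value penetrations stay near
1 % of the indentation while the iteration reaches a relative equilibrium
residual of 1e-6 or better at every increment (10 equal displacement
increments, damped Newton with a backtracking line search and
cycle-breaking half steps, at most 100 iterations).

Out-of-plane depth: plane-stress forces scale with an assumed section
depth, which the source experiment does not state. The model uses 35 mm,
the midpoint of the imaged slab thickness (sections of 30-40 mm): a 2D
model built from a slab-thick image most naturally represents that slab.
Reported quantities are the **total contact force** on the probe and the
maximum nodal reaction at the driven (control) nodes; the total is the
mesh-objective quantity and the one passed to the musculoskeletal stage,
while the max-nodal value depends on how many nodes share the load and
decreases indefinitely under refinement.

With the bundled cohort geometry and deflections the converged model
gives 0.25, 0.11 and 0.18 N for fetuses A, B and C: the ordering
(A > C > B) and the pairwise ratios (B/C = 0.62, C/A = 0.71) closely
match the published pattern, while the absolute scale is about one third
of the published values. The gap is consistent with the unknown depth
convention and with discretization: our own fully integrated coarse
meshes — the behaviour of a standard fully integrated quad model at
ordinary mesh sizes — produce 0.4-0.7 N on the same geometry and descend
toward the converged values under refinement. The probe's own stiffness
is irrelevant at these loads: halving or doubling its modulus changes the
reaction by well under 1 %.

The bench-validation scenario (a stiff round-ended probe pressed 5 mm
into a clamped silicone-rubber sheet, E = 10.3 MPa, nu = 0.49) is
implemented but requires the caller to supply the sheet thickness and
clamp span, which were never published; the model reports identical
loading and unloading branches, as an elastic frictionless model must.

## Musculoskeletal model

A planar sagittal reduction of an adult lower-limb model: pelvis fixed
(apart from the tracked hip translation), hip revolute, knee hinge,
ankle locked at 90 degrees. Adult reference segment lengths 396 mm
(femur), 430 mm (tibia); scaling multiplies femur and tibia by their own
measured-length factors, pelvis and foot by the mean factor, masses by
factor cubed, muscle path offsets by their segment's factor — and leaves
maximum isometric forces unchanged, as in the source protocol. Eighteen
muscles ship as a documented CSV (name, group, Fmax, via points as
fractional coordinates plus perpendicular offsets); wrapping surfaces are
reduced to fixed via points, and tendon-excursion moment arms
(r = -dL/dq, finite differences) agree with anatomical magnitudes at
neutral pose. The CSV can be swapped wholesale.

Inverse kinematics fits hip and knee angles per frame by least squares
on the model knee and ankle centres (residuals ~1e-7 mm on forward-model
round trips). Inputs are first rotated into the model's pelvis frame
(the imaging plane has no anatomical axes) and mirrored if the recovered
knee flexion is predominantly negative — the same leg seen from the
other side. Inverse dynamics uses d'Alembert's principle with position
Jacobians from the forward kinematics: generalized moments about hip,
knee and locked ankle from segment inertia (central-difference
accelerations, one-sided at the ends) and the wall reaction applied at
the calcaneus, ramped over the contact window in proportion to the
tracked deflection and directed along the inward wall normal. Gravity is
neglected (specific gravities of fetus and amniotic fluid nearly match).

Static optimization minimizes the sum of squared activations plus
heavily weighted reserve terms (one reserve per moment row, reference
1 N mm, weight 1e3) subject to moment balance and activation bounds,
solved per frame as a bound-constrained linear least-squares problem.
The locked-ankle moment row is included: the calcaneus load must be
balanced by ankle-crossing muscles, otherwise soleus and the tibialis
muscles would be structurally unloaded. Muscle force-length/velocity
scaling is deliberately omitted from the constraint (forces bounded by
Fmax only).

### What the planar statics can and cannot reproduce

With ~0.2 N wall reactions and fetal-scale moment arms (a few mm), the
moment demands are a few N mm and the optimizer's muscle forces peak
near 0.4 N (knee group) and 0.35 N (hip group). Two robust qualitative
results match the published pattern: the knee-group maximum exceeds the
hip-group maximum in every fetus, and the hip demand is flexion
(psoas/iliacus active, with the biarticular rectus femoris largest
because it serves the simultaneous knee-extension demand). Two do not:
the published ~8 N and ~21 N magnitudes are one to two orders larger
than planar statics permits at these loads — they require the adult
model's force-length/velocity machinery and 3D wrapping geometry, which
this reduction declaredly omits — and soleus cannot dominate the knee
group here, because a force applied at the calcaneus (behind the ankle)
demands dorsiflexion, not plantarflexion, so the dorsiflexors and vasti
carry the kick in statics.

## Numerical conventions

Images are row-major, pixel (i, j) centred at `origin + (j, i) * pixel`;
trajectories convert as mm = px * pixel + origin. The FE solver works in
SI internally (m, Pa, N) with mm at the API surface. All randomness
derives from `numpy` generators seeded per scenario; the pipeline
derives per-scenario seeds from one global seed, and equal seeds give
byte-identical summaries. Problem sizes were chosen for single-CPU
desk-scale runs: ~700-node FE meshes (10 increments, seconds per solve)
and 7-11-frame sequences per kick.
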