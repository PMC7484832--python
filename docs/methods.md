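# Methods

## Problem and frame conventions

A C-arm linac can collide with the treatment couch or the patient when
noncoplanar beams combine couch rotations (couch "kicks") with gantry
rotations. This package predicts those collisions at planning time from
three ingredients: a geometric model of the machine, a point-cloud model
of the patient, and a prediction of the couch readouts that will align
the selected treatment isocenter with the machine isocenter.

All geometry lives in an isocentric IEC-style frame, in cm:
`x1` lateral, `x2` vertical (up positive), `x3` longitudinal (toward
the gantry positive), origin at the isocenter. Gantry rotation by
`theta` applies

```
[[cos t, -sin t, 0],
 [sin t,  cos t, 0],
 [0,      0,     1]]
```

to every gantry-mounted point (rotation about the longitudinal axis);
couch rotation applies

```
[[cos t, 0, -sin t],
 [0,     1,  0    ],
 [sin t, 0,  cos t]]
```

(rotation about the vertical axis through the isocenter). Angles are
accepted on [-360, 360] degrees and normalized internally to
(-180, 180]; machine displays use the 0-360 scale. Translations are
`p' = p + m d` with `d` a unit direction.

## Machine model

- **Gantry head**: four coaxial cylinders stacked along the beam axis
  (vertical at gantry 0), bounded by five cap planes. The lowest plane
  is the isocenter-to-collimator clearance; radii grow away from the
  collimator face. Each cylinder is stored as two axis points plus a
  radius (equivalent to the two-axis-points-plus-circumference-point
  representation).
- **Imaging devices**: the MV imager (opposite the source) and the kV
  source/imager arms (orthogonal, on opposite lateral sides) are
  rectangular prisms rigidly attached to the gantry rotation, each
  parameterized by one extension distance ("vertical") from the
  isocenter. The kV arms deploy together.
- **Couch top**: a trapezoidal prism (wider at the foot end, mild
  taper) that translates per the LAT/LNG/VRT readouts and then rotates
  about the vertical isocenter axis. Translation-then-rotation matches
  how a pedestal couch rotates after patient alignment. For collision
  testing the couch is densified into surface points sampled on the
  prism faces at a configurable step (default 1 cm); corner points
  alone would miss mid-edge contacts.

Readout conventions: the lateral readout wraps at 0 / `lat_center_readout`
(default 1000) — readouts just below the center value are small positive
displacements, readouts just above zero are small negative ones; VRT is
the drop of the couch top below the isocenter; LNG is the couch index
(cm from the head end) of the point at the isocenter plane.

The shipped dimensions are **placeholders** with the proportions of a
modern C-arm machine (collimator clearance 40 cm, head radii 28-45 cm,
couch 230 x 47-53 x 9 cm); they are not measurements of any vendor's
hardware, and absolute collision boundaries computed with them are not
clinically meaningful. Real deployments load measured dimensions from a
YAML/JSON config.

## Couch-coordinate prediction

A radio-opaque marker under the CT couch top (laterally centered, a
known `depth_below_top` — default 4.1 cm — below the surface, at a known
linac couch longitude — default 140) maps CT image coordinates
`(X, Y, Z)` (x lateral, y down for a supine patient, z superior) to
linac readouts:

- `LAT = C - (X - X*)` if `X > X*`, `-(X - X*)` if `X < X*`, and the
  centered readout `C` exactly at `X = X*` (the branch the formulas
  leave open; the centered readout is the physically continuous choice);
- `VRT = Y* - Y - depth`;
- `LNG = L* - (Z - Z*)`.

`ct_to_couch_frame` applies the same correspondence to whole clouds, so
the closed loop *predict readouts -> convert to displacements -> pose
the couch* places the selected isocenter exactly at the origin; the test
suite verifies this to < 1e-9 cm over random isocenter selections.
Identical couch indexing between the CT and treatment couches is
assumed; couch sag and accessory offsets are not modelled.

## Patient model

The CT body contour (per-slice closed polygons, e.g. from DICOM
RT-STRUCT, optionally edge-resampled) is the accurate baseline. A depth
camera cloud is brought into the machine frame by a six-step block
calibration: identify four corners A, B, C, D of a block of known
dimensions; translate A to the origin; rotate edge AD onto the lateral
unit axis (minimal rotation: axis = cross product, angle = atan2);
roll about that axis to bring AC onto the longitudinal axis (which
carries AB onto the vertical axis for an orthogonal block); scale each
aligned axis by true/observed edge length; translate the origin to the
block center. The per-axis scaling makes the calibration affine rather
than rigid — intentional, because depth cameras exhibit axis-dependent
scale errors. Residual orientation error is removed by point-to-point
ICP against the CT contour: nearest-neighbour correspondences (k-d
tree), least-squares rigid (Kabsch) updates, relative-cost tolerance
1e-6, no outlier trimming by default (a trim fraction is exposed). The
per-iteration RMS cost trace is returned and is non-increasing by
construction. Merging keeps every point of both clouds with per-point
source labels; nothing is deleted by default.

With a default calibration block of 30 x 20 x 10 cm and isotropic corner
noise of sigma = 0.3 cm (the scale of a consumer depth camera's spatial
resolution at treatment-room distance), the *mean* residual over the
four reference corners is below 1 cm in >= 99% of seeded trials. The
mean is the package's recovery metric: the worst single corner is the
one that plays no role in fixing the roll about the first axis, and its
error scales inversely with the shortest block edge, so it reflects
block geometry more than algorithm quality.

## Collision detection

Everything reduces to one primitive: the signed dot product
`AB . AP` that tells which side of a plane (through `A`, normal `AB`) a
test point `P` lies on. Cylinder containment = between the two cap
planes and within the radius of the axis; prism containment = on the
interior side of all six face planes (outward normals derived from the
corners). Boundary points — zero dot product, distance exactly equal to
a radius — count as **inside**: every tie breaks toward predicting a
collision. The classification tolerance is 1e-9 cm.

Test points are the densified couch surface plus the patient cloud
(given in the couch home frame; the engine applies the couch
translations and rotation to the patient identically to the couch —
the patient rides with the couch). Test volumes are the four gantry
cylinders, evaluated by gating points between cap planes 1 and 5 and
then testing each plane-pair slab (a point within `margin` of a shared
plane belongs to both adjacent inflated cylinders), and each deployed
imaging prism via six dot products. A longitudinal pre-filter discards
points outside the superior/inferior extent of the active volumes plus
a guard band (default 1 cm) before testing; it is a pure speed-up whose
soundness follows from the volumes' own extents, and the suite asserts
filtered and unfiltered verdicts agree on seeded random scenes. An
optional isotropic `margin` (default 0) inflates every volume on top of
the already conservative geometry; verdicts are monotone in it.

The engine verdict is asserted bit-for-bit equal to a brute-force
oracle (every point against every volume, independent containment code:
Delaunay/convex-hull facets for prisms, cross-product axis distance for
cylinders) on 100 seeded random scenes.

Boundary sweeps advance one couch axis (lateral displacement or
rotation) linearly from a collision-free start until the first
collision, mirroring the in-room measurement procedure and guaranteeing
the first crossing is found even for non-convex clear regions. Default
steps: 0.1 cm lateral, 0.25 deg rotation — far below the couple-of-cm /
couple-of-degree conservatism margins such systems are designed around.
The returned bracket (last clear, first colliding readout) is exactly
one step wide. Lateral sweeps run in displacement space so the readout
wrap at 0/1000 never produces a discontinuous path.

Clearance maps evaluate the verdict on a (couch rotation x gantry
angle) grid; cells are independent, so adding patient points can only
turn clear cells into blocked ones (asserted), and a sagittally
symmetric phantom with a symmetric machine yields a map invariant under
`(rtn, gantry) -> (-rtn, 360 - gantry)` (asserted on a 36 x 72 grid).
Toggling deployed imaging devices in the fixed state turns the same map
into an imaging-angle availability chart. Plan verification iterates
control points through the identical verdict path.

## Synthetic data

The generators are pure functions of spec + seed and emit their ground
truth alongside the data:

- **Calibration block**: surface-sampled box with exact corner
  positions; the forward model for calibration tests distorts ideal
  corners by a known rotation, per-axis scale, and shift.
- **Cylinder phantom** (QA-array analog): lateral wall + caps, default
  26.6 cm diameter x 55 cm.
- **Humanoid phantom** (anthropomorphic analog): head/torso/legs as
  upper-half ellipsoids with centers on the couch-top plane, supine,
  head toward the gantry; half the points are generated on one side and
  mirrored, so the noiseless cloud is exactly bilaterally symmetric.
  The dimensions are textbook adult proportions serving as test
  fixtures, not anthropometry claims.
- **Scenes**: seeded random machine states with a phantom on the couch;
  `forced_collision` plants one point strictly inside a named volume
  (known verdict by construction), `forced_clear` uses a configuration
  whose every test point is geometrically below the gantry's reach.

Noise is isotropic per-point Gaussian, default sigma 0.3 cm. The
generators do **not** emulate depth-camera physics (occlusion,
quantisation, edge artefacts, self-shadowing), CT reconstruction, or
deformable anatomy — so passing tests demonstrate the geometry and
algorithms are correct, not that a specific camera meets a clinical
accuracy target.

## Numerical choices and problem sizes

- On-plane/boundary tolerance 1e-9 cm; construction-time planarity and
  convexity validation at 1e-6 cm.
- Sweep limit handling snaps values within 1e-9 of a motion limit onto
  the limit to avoid accumulated floating-point overshoot.
- The tangency acceptance check uses an upright cylinder phantom swept
  in couch rotation against the gantry stack at gantry 90; the analytic
  boundary is the root of a 2-D point-to-staircase distance (one box
  per gantry cylinder), found by bisection, and the sweep agrees within
  2 steps (0.5 deg) at 4 points/cm^2 phantom sampling.
- Suite sizes: 100 scenes for oracle equivalence, 500 calibration
  trials, 40 ICP trials, 50 closed-loop isocenters, 36 x 72 clearance
  grids at 1 cm couch sampling; the full suite runs in well under a
  minute on one CPU.

## Known limitations

- Containment is tested in one direction only: couch/patient points
  against gantry and imaging volumes. Thin gantry-side structures could
  in principle pass between sampled points; the conservative volumes
  and margin knob are the mitigation.
- The couch pedestal/base and immobilization accessories are not
  modelled; the gantry cylinder margin is assumed to encapsulate
  accessory trays.
- Placeholder machine dimensions: only relative/structural results are
  meaningful until a measured config is supplied.
- No continuous-time checking between control points, and no
  velocity-aware interlocks.
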