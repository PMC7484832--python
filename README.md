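# linac-cps

A collision prediction system (CPS) for noncoplanar radiotherapy
planning. Noncoplanar beams — couch rotations combined with gantry
rotations — can improve dose distributions, but planners avoid them
because a gantry–couch or gantry–patient collision discovered at the
machine means replanning. This package lets a medical physicist or
dosimetrist ask, at planning time: *for this patient, at these couch
coordinates, which combinations of couch rotation and gantry angle are
collision free?*

It provides:

- a geometric machine model — gantry head as a stack of four cylinders,
  MV/kV imaging devices as rectangular prisms, couch top as a
  trapezoidal prism — posed by the IEC rotation matrices

  ```
  gantry (about x3):  [[c, -s, 0], [s, c, 0], [0, 0, 1]]
  couch  (about x2):  [[c, 0, -s], [0, 1, 0], [s, 0, c]]
  ```

- a patient model built from the planning-CT body contour (DICOM
  RT-STRUCT or plain clouds) plus a depth-camera cloud, registered via
  a known-block calibration and point-to-point ICP;
- couch readout prediction from the treatment isocenter `(X, Y, Z)` and
  a couch-embedded reference marker `(X*, Y*, Z*)`:

  ```
  LAT = 1000 - (X - X*)   if X > X*,   -(X - X*) if X < X*
  VRT = Y* - Y - 4.1
  LNG = 140 - (Z - Z*)
  ```

  (all three constants are clinic configuration);
- a dot-product collision engine: a point is inside a volume iff every
  face-plane dot product and radial distance says so, with boundaries
  counting as collisions. It produces per-state verdicts with offending
  component pairs, boundary sweeps along couch axes, collision-free
  clearance maps over (couch rotation × gantry angle), and per-control-
  point plan verification;
- synthetic phantoms (calibration block, cylindrical QA-array analog,
  stacked-ellipsoid humanoid) so everything runs without any data
  download;
- ROC-style scoring of predicted vs observed collision outcomes
  (sensitivity, specificity, PPV, NPV).

The shipped machine dimensions are documented placeholders with
realistic C-arm proportions; clinical use requires in-room measured
dimensions supplied as a YAML/JSON config (`cps ... --machine-config`).

## Worked example

Predict couch readouts for an isocenter at CT `(3.2, 0.5, -5)` with the
couch marker at `(0.8, 15.0, 0)`:

```
$ cps predict-couch --iso 3.2,0.5,-5 --marker 0.8,15,0
{
  "lat": 997.6,
  "vrt": 10.4,
  "lng": 145.0
}
```

The isocenter sits 2.4 cm left of the couch midline (readout 997.6 on
the wrapped 0/1000 lateral scale), 10.4 cm above the couch top, and at
couch index 145.

With the gantry fixed at 90° and the couch at LNG 95 / VRT 16.6, rotate
the couch until the model predicts contact:

```
$ cps sweep --axis couch_rtn --direction +1 --state "gantry=90,lng=95,vrt=16.6"
{
  "axis": "couch_rtn",
  "last_clear": 29.0,
  "first_collide": 29.25,
  "clear_to_limit": false,
  "step": 0.25,
  "pairs": [["couch", "gantry_cyl_1"]]
}
```

The couch clears up to 29.0° and first touches the lowest gantry-head
cylinder at 29.25° (one 0.25° step later).

Map the collision-free space for a synthetic humanoid phantom:

```
$ cps synth humanoid --seed 5 --density 0.2 --noise 0 --out rando.xyz
wrote rando.xyz (1136 points)
$ cps map --patient-cloud rando.xyz --state "lng=100,vrt=12" \
      --rtn-grid="-90:90:10" --gantry-grid "0:350:10" --out map.csv
wrote map.csv (clear fraction 0.643)
```

`map.csv` holds a 19 × 36 grid of 0/1 cells (rows = couch rotation,
columns = gantry angle); 64.3% of the tested combinations are collision
free, with the blocked band around gantry 180° and at large couch kicks
toward the gantry. `--plot map.png` renders the same map.

Score a validation campaign of predicted-vs-observed outcomes:

```
$ cps evaluate --outcomes outcomes.csv
{
  "counts": {"tp": 88, "fp": 5, "tn": 18, "fn": 0, "total": 111},
  "metrics": {"sensitivity": 1.0, "specificity": 0.783,
              "ppv": 0.946, "npv": 1.0}
}
```

All of this is also available as a library (`import cps`); see
`docs/methods.md` for the model details, assumptions, and limitations.

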