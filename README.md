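# spinepose

3D localization of vertebral body centres from one calibrated pair of
biplanar radiographs (anterior–posterior + lateral), by feature-level fusion
in projective geometry.

Intraoperative biplanar X-ray gives two 2D projections of the spine but no
explicit 3D information, while navigation, 2D/3D registration, and spinal
geometry estimation all need 3D landmark positions. Triangulating
independently detected 2D landmarks uses the calibration only at the last
step and inherits every 2D detection failure. `spinepose` instead unprojects
learned 2D feature maps into a world-anchored voxel cube using the known
projection matrices, fuses the two views with learned channel weights, and
regresses 3D coordinates directly from the fused volume — the calibration
participates in the learning itself.

The pipeline, trained end to end:

```
x_AP, x_LAT ──shared 2D SCN──▶ M_i (H×W×K), h_i (H×W×L), w_i (K)
M_i, P_i    ──unproject+fuse─▶ V_agg = Σ_i w_i·V_i / Σ_i w_i   (D³×K)
V_agg       ──3D SCN─────────▶ V_processed (D³×L)
            ──softmax+soft-argmax──▶ y (L×3, world mm)
```

where the SCN (SpatialConfiguration-Net) is a two-branch network whose
local-appearance heatmaps are gated by a coarse spatial-configuration branch
to resolve the ambiguity between look-alike neighbouring vertebrae. The
loss combines per-view Dice + MSE heatmap terms with an L1 coordinate term
and a `−α·log V′(y_gt)` peak regularizer (α = 0.01).

Because no public calibrated biplanar dataset ships with the package, a
phantom simulator renders the training data: stacks of ellipsoidal
vertebral bodies in a soft-tissue cylinder, projected to DRR pairs under a
C-arm geometry (source–detector 2000 mm, isocenter 1000 mm, oblique angles
uniform in ±15°), with exact 2D/3D ground truth by construction. The
networks run on the package's own numpy/numba reverse-mode autodiff engine,
so everything trains on one CPU.

## Worked example

```bash
spinepose simulate --out data/ --seed 123 --phantoms 10,2,3 --pairs-per-phantom 4
spinepose train    --data data/ --out runs/desk --seed 0
spinepose evaluate --data data/ --run runs/desk --out runs/desk/eval --baseline
```

The first command renders 60 calibrated AP/LAT pairs (40 train / 8 val / 12
test, split by phantom) at 256×256 px with 3 vertebrae each. Training the
desk preset (80 epochs, ~15 min on one CPU) prints per-epoch losses and
periodic validation metrics; evaluation on the 3 held-out phantoms printed,
on this configuration:

```
pipeline  : IDrate 100.00% @ 5 mm | PEall 0.38 ± 0.16 mm | 12 images, 36 landmarks
baseline  : IDrate 66.67% @ 5 mm | PEall 58.37 ± 80.47 mm | 12 images, 36 landmarks
```

`IDrate` is the percentage of landmarks localized strictly within 5 mm of
ground truth; `PEall` is the pooled mean ± SD Euclidean error over all test
landmarks. The `baseline` row scores the coordinate-level alternative —
per-view argmax on the same trained 2D extractor followed by DLT
triangulation. On this run the 2D extractor barely responds to the most
caudal vertebra of one held-out phantom, so the baseline's argmax
triangulates nonsense for that channel (hence its heavy error tail), while
the fused volumetric path still localizes every vertebra to sub-millimetre
accuracy — the measured value of fusing the views at feature level rather
than at coordinate level. Sub-millimetre error is well below the 6.25 mm
voxel size of the regression cube: the soft-argmax reads out at sub-voxel
precision. `evaluate` also writes `metrics.json`, per-image IPE values, and
the cumulative IPE curve as CSV; `predict` exports per-landmark CSV and 3D
Slicer fiducial files.

The same objects are available as a library: `generate_dataset`,
`train`/`predict_sample`, `compute_metrics`, and the geometry layer
(`build_projection`, `project_point`, `triangulate`).

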