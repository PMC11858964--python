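# Methods

## Problem and model

`spinepose` localizes the 3D centres of vertebral bodies from one calibrated
pair of radiographic projections (an anterior–posterior and a lateral view).
Each view carries a 3×4 projection matrix `P = K[R|t]` mapping world
millimetre coordinates (isocenter origin, cranio-caudal z) to pixel
coordinates. The pipeline is feature-level multi-view fusion:

1. **Siamese 2D extractor** — a single 2D SpatialConfiguration-Net (SCN) is
   applied to both views. Its local-appearance branch is a 5-level U-Net
   whose top output is a K-channel feature map `M` at input resolution; a
   1×1 convolution plus sigmoid produces per-landmark heatmaps `h_la`. A
   spatial-configuration branch average-pools `h_la` by 4, applies three
   wide (7×7) convolutions and bilinear upsampling, and gates `h_la`
   multiplicatively: `h = h_la ⊙ h_sc`. The gating suppresses responses on
   look-alike neighbouring vertebrae, which is the classic SCN decomposition
   into candidate detection and spatial disambiguation. A third branch pools
   the bottom-level U-Net features and maps them through a dense layer and a
   softplus (+1e-4) to strictly positive per-channel fusion weights `w`.
2. **Spatial alignment fusion** — a 64³-voxel (32³ in the desk preset)
   axis-aligned cube of side 250 mm (200 mm desk) is anchored at the DLT
   triangulation of the two image-centre pixels. Every voxel centre is
   projected into each view and bilinearly samples `M` (zero outside the
   image), giving per-view feature volumes `V_i`; these are fused
   channelwise as the weighted average
   `V_agg[k] = Σ_i w_i[k] V_i[k] / Σ_i w_i[k]`.
   The unprojection is linear and differentiable in `M`; sample positions
   are fixed by the calibration.
3. **3D regression** — a 3D SCN (same two-branch structure with volumetric
   kernels) maps `V_agg` to L per-landmark volumes. A per-channel softmax
   over all voxels converts each to a probability mass, and the landmark
   estimate is its centroid over voxel-centre world coordinates
   (soft-argmax). Predictions are convex combinations of voxel centres and
   therefore always inside the cube.

The chain is differentiable end to end, so one objective trains both nets
jointly:

* per-view heatmap losses against Gaussian targets (peak 1, σ = 2 % of the
  image height): a channel-averaged Dice term (smooth constant 1e-5) to
  counter foreground/background imbalance, plus an MSE term, each summed
  over the two views;
* an L1 loss (mm) on the soft-argmax coordinates;
* a regularizer `−α·log V′(y_gt)` (α = 0.01) that maximizes the
  softmax-normalized volume at the ground-truth point (trilinear sampling,
  floored at 1e-12 before the log), ensuring a peak exists there.

The total is the plain sum of the four terms. Optimization uses Adam
(lr 1e-3, batch 4).

### Design choices where the architecture was open

* The 3D local-appearance head is **linear** (no sigmoid) so the spatial
  softmax can sharpen into a peaked distribution; a [0,1]-bounded volume
  would make the softmax nearly uniform over 32³ voxels and pin the
  soft-argmax to the cube centre. The 3D spatial-configuration gate remains
  sigmoid-bounded. In 2D both branch outputs are sigmoids so `h ∈ [0,1]`
  and the Dice term is well defined.
* The regularizer is evaluated on the **post-softmax** volume; the
  alternative (pre-softmax) reading is not shift-invariant and has no
  probabilistic interpretation.
* Decoder levels use a single 3×3 convolution after skip concatenation;
  encoder levels use two. Nearest-neighbour upsampling with skip
  concatenation; LeakyReLU(0.1) activations; He initialization.
* The spatial-configuration kernels (7×7 in 2D at 1/4 resolution, 3×3×3 in
  3D at 1/2 resolution) give receptive fields spanning more than one
  inter-vertebral gap (~30–40 mm), which is what the branch needs to encode
  ordering.
* Landmark correspondence is positional everywhere (channel l ↔ vertebra l,
  caudal to cranial); no matching step.
* DLT triangulation solves the stacked homogeneous system by SVD without
  Hartley normalization (pixel coordinates ≤ 1536 are well conditioned);
  degeneracy is declared when the second-smallest singular value falls below
  1e-8 of the largest. The returned point minimizes algebraic, not
  reprojection, error.

## Differentiable-array engine

The networks run on a compact reverse-mode autodiff engine over numpy arrays
(`spinepose.autodiff`), with numba-compiled direct convolution kernels
(`spinepose._kernels`). The engine covers exactly the operations the model
needs; convolutions are stride-1 zero-padded with odd kernels. Gradients of
every operation are tested against central finite differences in float64,
and the convolution forward pass is cross-checked against
`scipy.signal.correlate` and an independent im2col/GEMM implementation.
Training runs in float32.

## Synthetic data

Real acquisitions are emulated by an attenuation phantom: a caudal-to-cranial
stack of radio-dense ellipsoidal vertebral bodies (half-axes 15×12×10 mm,
centre-to-centre gaps uniform in 30–40 mm, per-vertebra lateral jitter
±5 mm, whole-stack offset ±8 mm), each with a fainter posterior ellipsoid
(attenuation 0.6 vs 1.0) that breaks AP/LAT symmetry, inside a soft-tissue
cylinder (radius 60 mm, attenuation 0.1). Landmarks are the body centres.

DRRs are rendered with the ideal acquisition geometry — source–detector
distance 2000 mm, source–isocenter distance 1000 mm, oblique (LAO/RAO)
angles uniform in ±15° about the nominal AP and LAT orientations — by
fixed-step ray integration (1 mm steps, trilinear interpolation through the
96³ voxel grid at 2 mm spacing) and min–max normalized to [0,1]. The
detector is 256×256 px over 360×360 mm in the desk preset. 2D ground truth
is the exact projection of the 3D landmarks, so the reprojection invariant
holds to machine precision by construction; the generator is a pure function
of (seed, config), and the train/val/test split is assigned per phantom so
no phantom appears in two subsets.

What the phantom does **not** model: scatter, beam hardening, detector
noise, anatomical shape variation beyond ellipsoids, soft-tissue
heterogeneity, and pathology. Passing the end-to-end test therefore shows
that the architecture can exploit calibrated projective geometry to recover
3D positions from consistent dual-view appearance — not that it reaches any
particular accuracy on clinical radiographs.

## Problem sizes and presets

The **desk preset** (default) runs the whole study on one CPU: 256×256
rendered images pooled 2× before the network (the projection matrices and 2D
targets are remapped exactly under pooling), K = 8 feature channels, L = 3
vertebrae, a 32³ cube of side 200 mm (voxel 6.25 mm), 2D U-Net widths
(8, 16, 16, 32, 32), 3D widths (4, 8, 16), 80 epochs over 40 training
pairs from 10 phantoms, validated every 5 epochs on 8 pairs (checkpoint
selection: best IDrate, ties by lowest PE), tested on 12 pairs from 3
held-out phantoms. A **full-scale preset** mirrors the hyperparameters a
GPU-scale study would use (K = 16, 64³ cube of side 250 mm, widths
(32, 32, 64, 64, 128), hundreds to thousands of epochs); it is provided as
configuration only.

## Metrics

PE is the per-landmark Euclidean error in mm; PEall pools mean ± SD over
every landmark of every test image (SD over landmarks). IPE is the mean PE
of one image; its cumulative distribution curve is reported on a threshold
grid. IDrate is the percentage of landmarks with PE strictly below 5.0 mm.
A landmark the baseline fails to detect in either view counts as not
identified and is excluded from PE averages (exclusions are reported). The
coordinate-level baseline detects per-view argmax pixels with the same
trained 2D extractor and triangulates them — the head-to-head comparison for
the value of feature-level fusion.

## Numerical notes and limitations

* Bilinear sampling aligns to pixel centres with zero padding outside;
  voxel-centre world coordinates everywhere.
* The weighted aggregation adds 1e-8 to the denominator defensively
  although weights are positive by construction.
* The DRR integrator's step error is bounded by step-halving convergence
  tests; doubling attenuation scales raw integrals exactly linearly.
* Fixed landmark count L: the channel count of both nets encodes vertebra
  identity, so a model is specific to its L.
* With 1 CPU the desk training run takes roughly 12–17 minutes; the phantom
  dataset renders in 2–4 minutes.
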