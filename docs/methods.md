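# Methods

## Problem and scope

`foveal3d` implements a complete pipeline for automatic localization and
volumetric segmentation of cervical lymph nodes on contrast-enhanced CT:
preprocessing, a multi-resolution ("foveal") 3D fully convolutional network,
patch-based training with three augmentation families, tiled full-volume
inference, and a node-level evaluation framework stratified by RECIST-style
short-axis diameter (SAD). Because clinical head-and-neck CT cohorts with
per-node ground truth are not publicly available, the package ships a
synthetic phantom generator with analytically known node geometry; every
stage of the pipeline is exercised end to end on phantoms.

## Preprocessing

Volumes are resampled to an isotropic grid (default 1 mm; linear
interpolation for intensities, nearest-neighbor for label maps so node
identities survive), cropped to a region of at least 200 x 200 x 250 mm
centered on the annotation bounding box (grown when annotations span more,
clamped to the volume), and normalized with a soft-tissue window/level.

The default window/level is 395/10 HU mapped linearly onto [-3, 3]. The
mapping is saturating: HU values outside [level - window/2, level +
window/2] clip to the interval bounds. Without clipping, bone (several
hundred HU) and air (-1000 HU) would land far outside the stated interval,
which would defeat the purpose of a normalization *to* an interval.

An automatic window estimator is provided as an alternative: it pools the
intensities of all node voxels plus a morphological dilation of the node
masks (default radius 3 mm, the "direct neighborhood"), and returns
`level = mean`, `window = 6 * std`, so that +-3 standard deviations span the
six-unit output interval. On soft-tissue statistics this lands near the
common CT soft-tissue window/level of ~350/50 HU. The fixed 395/10 window
is the default at train time; the estimator is opt-in (`--auto-window`).

Conventions: arrays are indexed (x, y, z) = (left-right,
anterior-posterior, inferior-superior), the axial plane is x-y, voxel
indices are 0-based voxel centers, and mm sizes convert to voxels by
rounding half away from zero.

## The foveal architecture

The network ingests a stack of patches centered at the same world point:
level 0 is small and at the finest spacing, each coarser level doubles the
spacing (`level_scale = 2`) and therefore covers a larger physical context
— high resolution at the fovea, coarse resolution in the periphery. Each
level runs `convs_per_block = 3` CBR units (valid 3x3x3 convolution, batch
normalization, ReLU). The feature-integration pathway merges coarse to
fine: the coarser map is upsampled by nearest-neighbor x2 (CBRU),
concatenated with the finer feature map, and fused by another CBR unit. A
final 1x1x1 convolution and a two-channel softmax yield per-voxel
foreground pseudo-probabilities; thresholding (default 0.5) produces the
binary mask.

Because all convolutions are valid, the output patch is smaller than the
inputs, and the per-level input sizes are determined exactly by the
requested output size: each 3^3 conv removes 2 voxels per axis, each x2
upsampling doubles the size. Not every output size is alignable across
levels — the pre-upsampling size must be divisible by the level scale at
every merge — and `required_input_geometry` raises a geometry error naming
the failing axis otherwise (`valid_output_sizes` enumerates the alignable
sizes). A forward shape simulation of the constructed network reproduces
the bookkeeping exactly; this is property-tested.

Choices the architecture description leaves open, fixed here and exposed in
`ModelGeometry`:

* **kernel 3x3x3** — the blocks operate on 3D patches, so the printed
  2D kernel size is realized in 3D;
* **channel widths** default (32, 64, 64, 64) over four levels; the
  desk-scale runs use a two-level (16, 16) instance;
* **merge rule**: upsample coarse, concatenate, CBR (sizes align exactly,
  no cropping needed by construction);
* **batch normalization** per channel with running statistics (momentum
  0.1) frozen at inference, so inference is deterministic;
* **padding** of out-of-volume foveal context with normalized air (-3.0),
  matching the air border of head/neck scans, rather than reflection.

The training patch is defined by its finest-level physical footprint
(72 mm in the clinical configuration). `output_size_for_patch_extent`
derives the largest alignable output size whose finest input fits that
footprint (58^3 for the four-level chain at 1 mm, input 66^3).

The network, including backpropagation and the AdaDelta optimizer, is
implemented directly in numpy (channels-last layout; convolution as one
GEMM per kernel offset). Analytic gradients are verified against finite
differences in the test suite.

## Training

Minibatches hold 12 patches drawn from distinct volumes whenever enough
volumes exist. To counter the extreme foreground/background imbalance,
exactly half the slots (round(12 x 0.5)) are foreground-guaranteed: their
centers are jittered around a uniformly chosen labeled voxel such that the
voxel stays inside the output window; the remaining slots are uniform over
the volume. Targets are the binary node masks on the output grid.

The loss is `0.5 * cross-entropy + 0.5 * (1 - soft Dice)` with
`softDice = (2 sum(p t) + eps) / (sum(p) + sum(t) + eps)` pooled over the
minibatch. The smoothing constant is `eps = 1e-5`: small enough that the
closed form for a uniform-0.5 prediction on an 8-of-64-voxel target equals
`0.5 ln 2 + 0.4 ≈ 0.7466` to four decimals, while keeping the
all-background case finite (empty target, empty prediction gives Dice
eps/eps = 1, loss 0).

Optimization uses AdaDelta (rho 0.95, eps 1e-6, lr multiplier 1). An
"epoch" is a fixed number of minibatches (configurable; patch-based
sampling has no natural dataset pass). Per-epoch training loss and a
validation Dice are logged; the validation Dice is a hard (argmax) Dice on
a fixed, seeded set of validation patches evaluated with frozen batch-norm
statistics — full-volume validation inference every epoch would dominate
the run time at desk scale. The best-validation checkpoint is retained
(and the log keeps the full curve, so final-epoch behavior remains
visible). All randomness flows from the config seed; identical configs
give bit-identical runs.

### Augmentation

Four strategies, applied on the fly per patch:

1. **affine** — object zoom drawn log-symmetrically in [1/1.2, 1.2]
   (only the upper bound 1.2 is prescribed; log-symmetry makes shrinking
   and growing equally likely) and per-axis rotations uniform in +-10 deg.
   Applied identically to every resolution level (per-level grids are
   isotropic, so the world transform has the same matrix in each level's
   index space); images linear, targets nearest.
2. **+ mirror** — sagittal (left-right) flip with probability 0.5 of image
   and target together, exploiting head/neck symmetry.
3. **+ B-spline** — local distortion from a 5x5x5 control-point grid
   spanning the patch. Control displacements are N(0, sigma) per axis with
   sigma expressed as a *fraction of the control-point spacing* (default
   0.2; the prescription is unitless, and this reading scales naturally
   with patch size — it is config-exposed). The dense field is the order-1
   (trilinear) B-spline interpolation of the control displacements, so
   every dense displacement is a convex combination of control
   displacements (tested as a hard bound). The distortion is applied to
   the finest-level patch and the target only: a fine-scale local
   deformation has no unambiguous realization on context patches of
   different physical extent, and what matters for training is exact
   image/target alignment on the grid where the loss is computed.
4. **+ mirror + B-spline** — all of the above (the strongest setting, and
   the default).

Augmentations never change grid shapes, spacing metadata, or target label
values — only their positions.

## Inference

The volume is covered by output-size tiles (default stride = tile size,
i.e. non-overlapping; trailing tiles clamp to the border and overlap).
Each tile's foveal context is sampled around the tile center with air
padding outside the volume. Overlapping predictions are averaged
arithmetically. The threshold on the probability map defaults to 0.5 (the
cutoff is not prescribed anywhere; it is config-exposed since the
FP/sensitivity trade-off depends on it directly).

## Evaluation

Connected components of the binary prediction (face/6-connectivity by
default; 26 available) are computed; components smaller than 3^3 = 27
voxels are excluded from all metrics (at 1 mm their SAD is clearly below
the 5 mm annotation floor). A 26-voxel component is filtered, a 27-voxel
component retained.

**Matching** is any-overlap: a ground-truth node is localized iff at least
one retained predicted voxel lies inside it, and a component is a true
positive iff it overlaps at least one node — a single component may credit
several touching nodes, which is exactly the situation (conglomerate
nodes) that motivates per-node *sensitivity* instead of per-node Dice. No
overlap threshold is prescribed; any-overlap is the weakest reading of
"correctly identified", and a minimum-overlap-fraction knob (default 0) is
exposed for sensitivity analyses.

Metrics:

* **LR** — percentage of localized nodes; reported as the mean of
  per-volume LRs (scan-level convention) and pooled over nodes
  (node-level convention, `detected/total` per SAD group);
* **FP/V** — retained components overlapping no node, per volume;
* **global TP-only Dice** — per volume, between the union of TP-component
  voxels and the *full* ground-truth foreground: FP components are
  excluded from the prediction side, but missed nodes still penalize the
  score (the alternative, restricting ground truth to localized nodes, is
  config-exposed and non-default);
* **node sensitivity** — covered fraction of each node's voxels.

**SAD measurement**: per axial slice of a voxel set, the long axis is the
maximal Feret diameter of the cross-section (farthest pair of voxel
centers) and the short axis the extent of the projections onto the
perpendicular in-plane direction, plus the voxel footprint along that
direction (a single voxel measures one voxel, not zero); the SAD is the
maximum short axis over slices. This mirrors the radiologist's axial
RECIST measurement; the rasterization convention biases measurements
upward by up to about half a voxel, which is inside the +-1 voxel contract
the phantom tests enforce.

Nodes below the 5 mm annotation floor (measured SAD) are excluded from LR
denominators; by default a component overlapping *only* such nodes counts
as an FP — mirroring the inflated raw FP rates that motivate a reader
review — while a review mode reclassifies them as small-node TPs. The
review arithmetic itself (total findings minus re-identified small nodes,
minus true nodes outside the annotated region, minus unclear findings) is
implemented as `false_positive_review`; for the clinical counts
459 - 268 - 36 - 13 it yields 142 residual FPs. Note the published
post-review rate (2.4 FP/volume) is not reconstructible from 142 findings
over 30 scans alone (142/30 ≈ 4.7); the review also considered sub-27-voxel
findings, so the two denominators differ, and only the explicit count
arithmetic is reproduced here.

## The phantom generator

Phantoms emulate the features of contrast-enhanced neck CT that the
pipeline is sensitive to, with defaults chosen once as a realistic desk-
scale testbed:

* grid 64^3 at 1 mm isotropic (anisotropic input spacing such as
  0.5 x 0.5 x 1 mm is exercised by the resampling tests);
* an air border and an elliptic soft-tissue body (fat field, -80 HU);
* muscle blocks (~50 HU) — nearly isodense with nodes, the clinically
  confusable case; bone cylinder (500 HU); vessel-like bright tubes
  (150-300 HU) as designed false-positive bait (round in the axial plane
  but elongated);
* 5-10 nodes per volume with log-normal SADs (median 8 mm, sigma 0.45,
  clipped to 4-18 mm at this grid size; the clinical distribution spans
  ~3-45 mm with mostly sub-centimeter nodes), node intensity ~N(60, 15) HU
  per node — inside the 395/10 window;
* optional conglomerates (nodes placed touching, so they merge into one
  connected component) with configurable probability; with probability 0 a
  one-voxel moat keeps isolated nodes non-adjacent;
* additive Gaussian HU noise (default sigma 10).

Nodes are ellipsoids rotated only within the axial plane, so the requested
SAD is exactly twice the smaller in-plane semi-axis and the measured SAD
recovers it to within one voxel. This is the reason for restricting
rotation: a freely tilted ellipsoid changes its axial cross-section and
the requested SAD would no longer be the analytic truth. Lobulated or
necrotic node shapes, contrast phases, and imaging artifacts are out of
scope; consequently, passing phantom tests demonstrates the correctness of
the pipeline mechanics and learnability of intensity+shape discrimination,
not clinical-grade performance on real CT.

All randomness flows from a single per-volume seed; a cohort derives
per-volume seeds as `base_seed + index`.

## Scaled-down end-to-end run

The clinical configuration (hundreds of scans, four resolution levels,
2,000 epochs) is far beyond a single-CPU desk run, so the end-to-end path
fixes its own reduced study conditions: 20 phantoms (64^3, 1 mm; split
14 train / 3 validation / 3 test), a two-level geometry with (16, 16)
channels and 16^3 output tiles, 20 epochs x 15 minibatches = 300
minibatches of 12 patches, strongest augmentation, threshold 0.5. Against
the held-out phantoms this run is required to reach a global TP-only Dice
of at least 0.6 and a pooled LR of at least 80% for nodes >= 10 mm —
deliberately modest bars that establish the pipeline learns and localizes
at toy scale; they say nothing quantitative about clinical data. The
published clinical scores (e.g. test LR 81.1% per volume, Dice 0.71) are
not reproducible without the clinical dataset and GPU-scale training and
are not targets of this package.

## Known limitations

* The numpy network is CPU-bound; clinical-scale training is out of scope.
* Weight-level fidelity to the original model is not claimed: exact
  channel widths of the published instance are unstated, and no trained
  weights are available.
* The SAD convention (Feret long axis + perpendicular extent, max over
  slices) is one defensible formalization of the manual RECIST
  measurement; alternatives (e.g. minimal-width calipers) can differ by a
  fraction of a voxel.
* Phantom realism is deliberately limited (see above).
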