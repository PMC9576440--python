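# Methods

`ctlungseg` implements a three-stage pipeline for lung segmentation in
pediatric (preschool-age) chest CT, where three properties of the data
break segmenters tuned on adults: the thorax covers less than 20 % of
the 512×512 frame, patient motion produces streak artifacts, and failed
breath-holds collapse localized lung regions toward soft-tissue
density. The package also ships a synthetic phantom generator that
reproduces exactly these three challenges, so the full pipeline is
trainable and testable without clinical data.

## Stage 1 — preprocessing (crop-and-zoom)

Each slice is smoothed with an isotropic 2D Gaussian

G(x, y) = (1/σ√2π) · exp(−(x² + y²)/2σ²),  σ = 3 px,

which suppresses acquisition noise while keeping lung boundaries sharp.
The body is then located per slice: intensities are clipped to the HU
window (−1000, 400), thresholded at −300 HU (soft tissue vs air), the
binary image is opened with a disk of radius 3 px to detach thin
table/blanket bridges, and the largest 8-connected component is taken
as the body. The union of the per-slice circumscribed rectangles (plus
a 4 px margin) defines one crop box per case, so the thorax is framed
consistently across slices; the crop is resampled to 256×256 (bilinear
for the image, nearest-neighbour for masks). The transform is recorded
and invertible, so predictions are always scored in original
coordinates.

Numerical choices: reflect padding for the Gaussian (no dark halo at
the frame edge); 0-based half-open (row, col) coordinates throughout;
an all-air case raises a "no body found" error carrying the case id
rather than producing an empty crop. The threshold and window values
are this package's own choices — they only need to separate a −1000 HU
background from a ≥ −300 HU body, which holds for any calibrated CT.

## Stage 2 — the ResUnet and its loss

The network is a U-shaped 2D encoder–decoder whose basic block is
*concatenative*: two 3×3 conv + batch-norm + Leaky-ReLU (slope 0.01)
stages produce `filters` feature maps that are concatenated with the
block's input, so a block maps C → C + filters channels. This retains
the original-resolution features alongside the convolved ones and is
the sense in which the architecture is called "ResUnet" here — a dense
shortcut by concatenation, not an additive residual. Downsampling is
2×2 max-pooling; upsampling is nearest-neighbour ×2 followed by a 1×1
channel-reducing convolution (an exact, cheap choice whose blockiness
is immediately smoothed by the following 3×3 convolutions); skip
connections concatenate encoder features into the decoder. Dropout
(rate 0.2) acts on the two deepest levels. A 1×1 projection + sigmoid
emits a per-pixel lung probability, binarized at 0.5.

Defaults are depth 4 / base 32 channels for 256×256 crops; the reduced
benchmark configuration is depth 3 / base 8 for 128×128. Depth and
width are configuration, chosen per input scale.

The training objective combines overlap and pixel terms:

L_Dice(e, f) = 1 − (2·Σef + s)/(Σe + Σf + s)     (s = smooth)
L_f = mean over pixels of  −ɑ(1−y′)^r log y′  (y = 1)
                            −(1−ɑ) y′^r log(1−y′)  (y = 0)
L_all = α · log(max(L_Dice, ε)) + L_f,   α = 0.3, ε = 10⁻⁴

with focal defaults ɑ = 0.25, r = 2 (the original focal-loss values;
the formulation names both symbols but fixes neither), natural
logarithms, and mean reduction over pixels for batch-size independence.
The `log_floor` clamp ε is required: log L_Dice diverges to −∞ at
perfect overlap, and the clamp keeps the objective finite without
changing its ordering away from the optimum. The smooth constant
appears in numerator and denominator alike so a perfect prediction
scores exactly 0 for any s.

Training follows the study protocol: RMSprop (ρ = 0.9) with initial
learning rate 0.001, 10 epochs, batch size 8, data shuffled with the
run seed, no augmentation. The test split is case-level (no slice of a
held-out case ever enters training); the train/validation split is
image-level at fraction 0.9 within the remaining cases, matching the
source protocol's picture counts. The checkpoint with the best
validation Dice is kept.

### The autodiff engine

No deep-learning framework is a dependency: `ctlungseg.nn` is a small
reverse-mode automatic-differentiation engine over NumPy arrays, with
convolution as im2col + GEMM so the heavy arithmetic runs inside BLAS,
a fused closed-form backward pass for batch normalization, and an
RMSprop optimizer. Every operator's gradient is validated against
central finite differences (float64, relative tolerance 10⁻⁴) and
convolution against an independent `scipy.ndimage.correlate` oracle in
the test suite. Training runs in float32; gradient checks in float64.

## Stage 3 — case-based 3D component filter

Because the model segments slices independently, a case's stacked
prediction can contain spurious 3D blobs (table edges, streaks,
pre-scan frames). The filter labels the stacked binary mask in 3D
(26-connectivity by default, 6 available), sorts components by volume
with deterministic tie-breaking by first-voxel scan order, and keeps at
most the two largest whose in-plane centroids lie within the central
80 % of the cropped frame — the crop already centres the thorax, so
peripheral components are artifacts. The filter is idempotent, only
ever removes voxels, and degenerate inputs (empty prediction, nothing
central) yield an empty mask plus an explicit warning record. There is
deliberately no absolute minimum-volume rule: selection is by size rank
and location only. A voxel-removal filter cannot literally re-create
lung tissue lost to a breath-hold defect; what it preserves is the two
lungs as single 3D bodies bridging defective slices, which is the
property the tests assert on dropout phantoms.

## Evaluation

Per case, in original coordinates: voxelwise confusion counts give
IOU = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN), precision = TP/(TP+FP),
recall = TP/(TP+FN), with the identity Dice = 2·IOU/(1+IOU) asserted
for every computed case. Reports are macro-averages (unweighted means
over cases) with one row per case plus an Average row. Conventions:
empty-vs-empty scores 1.0 on all four metrics; empty-vs-nonempty
scores 0.

## The phantom generator

A phantom case is an axial stack with: air background (−1000 HU), a
bright table band (+300 HU) outside the body, an elliptical
soft-tissue body (+40 HU) with a thin bone rim (+400 HU) whose area
fraction defaults to 0.18 of the frame (the pediatric "small chest"
regime), and two elliptical lungs (−800 HU) whose in-plane radii taper
toward apex and base so the pristine ground-truth mask always has
exactly two 3D components. Three defect processes are parameterized and
logged per slice:

* **streaks** — oriented Gaussian-profile lines added in HU (default
  amplitude 80 HU) on a random subset of slices; image only, mask
  untouched;
* **breath-hold dropout** — with per-slice probability 0.1, a
  contiguous disk inside one lung is raised to soft-tissue intensity
  and removed from a *degraded* working mask while the pristine mask is
  kept as gold standard, mirroring how clinicians annotate the full
  lung;
* **additive Gaussian noise** (default σ = 20 HU).

Defaults were chosen once as plausible desk-scale analogues of the
three clinical phenomena; the HU palette places the contrasts exactly
where the preprocessing thresholds must discriminate. Identical spec +
seed reproduces a phantom bit-for-bit. What the phantoms do **not**
emulate: real anatomy (lobes, airways, vasculature, mediastinum),
scanner physics (beam hardening, partial volume, dose-dependent noise
texture), pathology, or inter-patient variability. Passing the phantom
benchmark therefore demonstrates that the pipeline's machinery is
correct and that its stages compose as designed — not clinical-grade
accuracy on real pediatric CT.

## Benchmark scale and ablation

The end-to-end benchmark trains the reduced configuration (base 8,
depth 3, 128×128 crops) on 32 phantom cases of 10 slices at 192×192:
12 cases are held out case-level, leaving 200 train+validation slices,
and the protocol above (10 epochs, RMSprop 0.001, combined loss
α = 0.3) runs on one CPU in a few minutes. The fitted pipeline reaches
a macro-average Dice above 0.99 on the held-out cases, and the case
filter never lowers the mean Dice. The ablation baseline is a plain
U-Net (standard double-conv blocks), trained on whole frames resized to
128 without the body crop, with plain Dice loss, and evaluated without
the case filter — i.e. none of the three stage-level contributions —
under the identical split and budget; the full pipeline's mean Dice is
asserted to be at least the baseline's.

## Known limitations

* The phantom geometry is convex and high-contrast; the reported
  phantom scores are upper bounds on what identical machinery would
  achieve on clinical data.
* The network is strictly 2D; volumetric context enters only through
  the 3D component filter.
* The combined loss is unbounded below only via the clamp; with very
  small `log_floor` values the Dice term can dominate late training.
* Left/right anatomical labeling, lobe separation and airway removal
  are out of scope; the filter returns "the two largest central
  volumes", not labeled lungs.
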