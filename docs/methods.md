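# Methods

This note records the scientific and numerical choices behind
`smallseg`: what is modeled, which parameters matter, and what the
bundled synthetic data can and cannot demonstrate.

## Problem setting

The target task is segmentation and case-level detection of small
metastatic brain tumors in axial T2-FLAIR MRI under severe data
scarcity.  "Small" is defined by cross-sectional area, not diameter
(some metastases are long and thin): a case is *small-tumor* when the
largest per-slice lesion area across the stack is **below 3.5 cm²**,
computed at the native in-plane resolution before any resampling.  The
area of a 2 cm diameter circle (the conventional large-metastasis
cutoff) is just under this threshold.  Tumor-free cases are scored by
detection only; several of them carry white-matter hyperintensities,
bright FLAIR foci that are the dominant source of false positives.

## Preprocessing

Clinical-style series go through the standard DICOM grayscale chain:

1. **Modality LUT** `v = m·v_org + b0` with the stored rescale
   slope/intercept, mapping stored pixel values to physical units.
2. **VOI LUT**, the simplified piecewise-linear window
   `G(v) = 0` below `c − w/2`, `gm` above `c + w/2`, and
   `(gm/w)·(v + w/2 − c)` inside.  Values exactly at the window edges
   fall on the linear branch, so `G` is continuous and non-decreasing.
   This deliberately implements the simple linear dialect, not the
   DICOM standard's `(w−1)/(c−0.5)` variant.
3. **Presentation LUT**: per-case min-max rescale to integer 12-bit
   range [0, 4095]; a constant input maps to 0.

Polygon tumor annotations (closed polylines keyed by SOPInstanceUID)
are rasterized by even-odd polygon fill; the fill includes the polygon
boundary, and annotation stroke widths above one pixel add a dilated
boundary stroke.  Keeping width-1 strokes implicit in the fill avoids
systematically inflating few-pixel lesions, which would otherwise bias
the small/large classification.

Stacks of 24–25 slices are doubled by cubic-spline interpolation along
the slice axis (the interpolant reproduces the originals exactly at
even output indices; labels are interpolated and re-binarized at 0.5).
A 25-slice stack arithmetically yields 49 slices; the final slice is
dropped so every case lands in the 47–51 range.  Stacks are then
zero-padded at the end to 64 slices and resampled in-plane to 128×128
(trilinear for images, nearest-neighbor for labels).  The size class
is computed and frozen *before* interpolation and resampling.

BraTS-style volumes (240×240×155, labels {0,1,2,4}) are decimated with
`u_i = s[16 + 2i]` for 64 output slices — the first 15 slices of such
volumes are blank, and the decimation start index follows the stated
rule literally — then labels 1/2/4 are merged into a single foreground
class and the volume is resampled in-plane.

## Architectures

Both networks map `1×H×W×D` inputs (dims multiples of 32) to 2-channel
logits; segmentation is the argmax, with ties resolved to background so
inference is deterministic and specificity-friendly.

**U-net.** Five encoder blocks of {stride-s conv → instance norm →
ReLU, stride-1 conv → instance norm → ReLU} with a projected residual
bypass.  The first block runs at stride 1 (1→16 channels at full
resolution); blocks 2–5 run at stride 2 and double channels, so the
default bottleneck is 256×8×8×4 for a 128×128×64 input.  Four decoder
blocks of {stride-2 transposed conv, skip concatenation, conv +
instance norm + ReLU, projected residual from the concatenation}
return to 16×128×128×64 before a 1×1×1 head.  `base_channels` scales
the whole ladder proportionally.

**Swin-transformer U-net.**  The encoder is a stride-2 convolutional
patch embedding (feature size 48) followed by five stages of paired
attention blocks — layer norm → windowed multi-head self-attention →
layer norm → MLP, then the same with shifted windows — where stages
two through five begin with patch merging (2×2×2 neighborhood
gathering + linear 8C→2C), doubling channels and halving resolution.
The channel ladder is 48–96–192–384–768 with bottleneck 768×4×4×2.
Five decoder blocks (stride-2 transposed conv, concatenation with the
matching encoder feature passed through a residual conv sub-block,
fusing residual sub-block) end at 48×128×128×64 before the head.
Head count per stage is `C/16` (minimum 1).  Two standard Swin details
are deliberately omitted: relative position bias, and the boundary
attention mask for shifted windows (cyclic shift is used as-is).
Neither affects any shape or freezing contract; they trade a small
amount of modeling fidelity for a substantially simpler attention
kernel.  Window size defaults to 4 and is clamped per stage to the
available resolution; no shift is applied along an axis the window
already covers.

**Parameter groups.**  Every trainable parameter belongs to exactly
one of {encoder, decoder, bottom_two, head}.  "Bottom two" means the
two decoder blocks nearest the output; the freezing policies are
`all`, `decoder_only` (encoder frozen — the SSL downstream protocol)
and `bottom_two_only` (everything frozen except the bottom two decoder
blocks and the channel-reducing head — the layer-freezing transfer
protocol).

**Numerical substrate.**  Both networks run on `smallseg.nn`, a
compact reverse-mode autodiff engine over float32 numpy arrays.  3D
convolution is evaluated as one batched matmul per kernel offset
(27 for a 3³ kernel), which keeps peak memory at one output-sized
temporary; transposed convolution uses kernel = stride = 2
(non-overlapping).  Gradients of every primitive are verified against
central finite differences in the test suite.  Inference runs under a
`no_grad` context that builds no graph, so a full-size Swin forward
pass fits comfortably in a few GB and takes on the order of a minute
or two on one CPU core.

## Self-supervised pretext task

Each unlabeled volume yields two corrupted views: the *inner* view
replaces six rectangles (sides 5–32 px) drawn entirely from the
central half of the in-plane extent, the *outer* view replaces six
rectangles (sides 20–64 px) that intersect the border band (outer
quarter).  Rectangles are 2D, replicated across a random contiguous
slab of slices so the corruption is volumetric, and filled with
uniform noise over the volume's observed intensity range (replacing,
not additive).  Voxels outside the rectangles are bit-identical to the
original — asserted in tests.

Both views pass through the Swin encoder.  The contrastive term is the
normalized-temperature cross-entropy (NT-Xent) over in-batch
negatives, computed by default on spatially pooled bottleneck features
passed through a two-layer projection head (temperature 0.5); the
variant that contrasts the reconstructed images directly is selectable
(`contrast_on="image"`), since the two-view reconstruction framing
admits either reading.  The second term is the L1 distance between the
outer-view reconstruction and the uncorrupted original.  The combined
loss is `contrastive + λ·L1` with λ = 1 by default.  At the
identical-embedding point the contrastive loss equals `ln(2N−1)` for
batch size N, which the tests use as a closed-form oracle.  Downstream,
the pretrained encoder is loaded and frozen and only the decoder
trains, on augmented small-tumor cases.

## Augmentation

Four in-plane transform kinds, applied identically to every slice of a
case: rotation by a magnitude uniform in [20°, 50°] with random sign;
scaling uniform in [0.6, 0.9] ∪ [1.1, 1.5] (near-identity scales are
outside the legal ranges by construction); rotation+scaling combined;
and a fixed 0.4 shear.  Images are resampled linearly, labels
nearest-neighbor; out-of-field regions are zero-filled.  An
augmentation rate of N means the training set grows to N× its size:
each original is kept once and receives N−1 variants, cycling uniformly
over the four kinds.  Test folds are never augmented, and augmented
variants inherit their source case id so they can never leak across a
cross-validation split.

## Training and evaluation

The segmentation loss is soft Dice over both channels (cross-entropy
selectable); the optimizer is Adam.  The full-scale protocol uses a
100-epoch budget with fine-tuning budgets of {2, 4, 6, 8, 10} epochs
(default 6); the bundled experiments use much smaller budgets — see
"Problem sizes" below.  Cross-validation is three-fold (three
near-equal random subsets) or leave-one-out.  Normal cases never enter
training in detection experiments; tumor cases receive their detection
decision from the fold in which they were held out, and normals are
scored with a model trained on all tumor cases.

Dice uses the both-empty = 1 convention (a correct all-negative
segmentation is not penalized; normals are scored by detection, not
Dice).  A case counts as "tumor detected" when some 26-connected
predicted component reaches `min_component_voxels` (default 1 — any
predicted voxel; configurable to study the specificity trade-off,
since the case-level criterion is otherwise underdetermined).
Sensitivity and specificity are reported as percentages rounded
half-up to one decimal; undefined ratios are reported as undefined,
never as zero.

## Synthetic phantoms

The generator emulates the *statistical structure* the pipeline
depends on, not MRI physics.  Brains are axis-aligned ellipsoids with
low-frequency multiplicative texture plus Gaussian noise; lesions are
ellipsoids with a smooth intensity falloff toward the rim, so the
equatorial per-slice area is the analytic ellipse area π·a·b and the
3.5 cm² class rule can be enforced exactly at sampling time.  Small
lesions are sampled log-normally around the 1.1 cm² cohort median and
capped at 2.6 cm²; large lesions start at 4.2 cm².  The gap around the
3.5 cm² threshold is deliberate: pixelation and the polygon-annotation
round trip perturb measured areas by up to a few tenths of a cm², and
the margins guarantee the class survives preprocessing.  Slice counts
are drawn from 47–51 with roughly one case in eight at 24–25; pixel
spacing defaults to 0.9 mm (a realistic head-MRI value that puts a
median small lesion at ~13 pixels across at 256², reproducing the
few-pixel regime after resampling to 128²).  Raw stored values relate
to physical intensities through a rescale slope/intercept (defaults
2 / −1024), and window center/width (700/1400) cover the tissue+lesion
range.  Hyperintensity speckles are small bright blobs (< 0.3 cm² per
slice) added only to normal cases and never to the truth mask.
BraTS-like volumes carry one large three-compartment lesion (necrotic
core 1 inside enhancing 4 inside edema 2) and blank first 15 slices at
the 155-slice default.

What passing tests on phantoms shows: the preprocessing chain
preserves geometry and size class end to end; the networks can learn
bright-ellipsoid segmentation at desk scale; augmentation helps in the
low-data small-lesion regime; the freezing and SSL protocols hold
their contracts.  What it does not show: performance on real FLAIR
anatomy — no bias fields, no skull, no multi-focal or infiltrative
lesion shapes, no scanner variation — so phantom Dice values say
nothing quantitative about clinical Dice.

## Problem sizes

The bundled tests and the acceptance script are sized for a single CPU
core: training experiments run U-nets with 2–4 base channels on
32³–64×64×32 volumes for 6–10 epochs (a scaled-down, shape-preserving
version of the full 16-channel / 128×128×64 / 100-epoch protocol), the
preprocessing round-trip check uses 100 phantoms at 128² resolution,
and the architecture contracts are verified on real full-size forward
passes.  The full-scale training configuration remains available
through the same estimators for users with the real datasets and more
compute.

## Known limitations

* The slice-interpolation reference method is realized as a cubic
  spline behind a pluggable interface; higher-order schemes can be
  substituted.
* The Swin attention omissions noted above (no relative position bias,
  no shift mask).
* Validation-based model selection is not used at leave-one-out scale
  (no spare validation data); final-epoch weights are taken.
* The both-empty Dice convention and the 1-voxel detection default are
  package decisions where the underlying criteria are underdetermined;
  both are configurable.
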