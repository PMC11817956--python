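# smallseg

Segmentation and case-level detection of **small metastatic brain tumors**
in 3D T2-FLAIR MRI, built for the data regime a medium-scale hospital
actually faces: a few dozen annotated in-house cases, supplemented by a
large public primary-tumor dataset.

Small metastases are the hard case for segmentation networks.  A lesion
whose largest cross-section is under 3.5 cm² spans only a handful of
pixels after volumes are resampled to network resolution, and the Dice
score itself is biased against small objects: for a fixed one-pixel
boundary offset,

```
Dice = 2·TP / (2·TP + FP + FN)
```

evaluates to 0.44 for a 3×3 object but 0.64 for a 5×5 one.  This package
implements a full, tested pipeline for studying that regime:

* **Preprocessing** — the DICOM grayscale chain (modality LUT
  `v = m·v_org + b0`, piecewise-linear VOI windowing with slope `gm/w`,
  per-case 12-bit presentation normalization), JSON polygon-annotation
  rasterization, cubic-spline slice doubling for thin stacks,
  zero-padding to 64 slices, and in-plane resampling — every case ends
  as a canonical 128×128×64 image/label pair.  BraTS-style labeled
  volumes are decimated (`u_i = s[16 + 2i]`, 64 slices) and their
  {1, 2, 4} labels merged to a single foreground class.
* **Models** — a residual 3D U-net (16→256 channels, bottleneck
  256×8×8×4) and a Swin-transformer U-shaped network (patch embedding +
  four patch-merging stages with W-MSA/SW-MSA pairs, bottleneck
  768×4×4×2, final decoder feature 48×128×128×64), both scale-configurable
  and both running on the package's own numpy autodiff engine
  (`smallseg.nn`) — no deep-learning framework required.
* **Self-supervised pretraining** — dual cutout-corrupted views (inner
  5–32 px rectangles in the image core, outer 20–64 px rectangles on the
  border band, six of each), an NT-Xent contrastive term between the two
  views and an L1 reconstruction term against the uncorrupted original.
* **Training strategies** — supervised learning with geometric
  augmentation (rotation ±20–50°, scale 0.6–0.9/1.1–1.5, shear 0.4, at
  rates 1/4/8/16/32), transfer learning with full fine-tuning or
  bottom-two-layer freezing, and frozen-encoder SSL downstream training;
  three-fold and leave-one-out cross-validation.
* **Evaluation** — voxel Dice, connected-component case detection, and
  cohort sensitivity/specificity including the variant that excludes
  normals with white-matter hyperintensities (the dominant false-positive
  source).
* **Synthetic phantoms** — an ellipsoidal brain-phantom generator that
  emulates the study cohort (18 large / 15 small / 22 normal cases, small
  lesions < 3.5 cm² with median ≈ 1.1 cm², 47–51 slices with a minority
  at 24–25, 12-bit grayscale, hyperintensity speckles) so the entire
  pipeline is testable without any data download.

Everything is exposed as scikit-learn-style estimators
(`UNetSegmenter`, `SwinUNETRSegmenter`, `ContrastivePretrainer`) with
`fit`/`predict`/`get_params`, plus thin functional wrappers.

## Worked example

Train a desk-scale U-net on twenty synthetic large-lesion cases
(64×64×32 voxels) and score the six held-out cases:

```python
import numpy as np
from smallseg.phantom import generate_toy_canonical
from smallseg.models import UNetSegmenter
from smallseg.metrics import dice, dice_offset_study

cases = [generate_toy_canonical((64, 64, 32), "large", seed=i) for i in range(20)]
X = np.stack([c.image for c in cases])
y = np.stack([c.label for c in cases])

est = UNetSegmenter(base_channels=4, epochs=10, lr=3e-3, batch_size=4,
                    random_state=0).fit(X[:14], y[:14])
scores = [dice(p, t).dice for p, t in zip(est.predict(X[14:]), y[14:])]
print("mean held-out Dice:", round(float(np.mean(scores)), 3))
print("offset study sides 3..8:", [round(v, 2) for v in dice_offset_study(range(3, 9))])
```

prints

```
mean held-out Dice: 0.675
offset study sides 3..8: [0.44, 0.56, 0.64, 0.69, 0.73, 0.77]
```

The mean Dice of 0.675 shows the scaled-down network segments large
synthetic lesions well; the offset study prints the Dice a square of
side 3..8 earns against its own copy shifted one pixel diagonally —
the small-object penalty in its purest form.

A full cohort can be synthesized and preprocessed from the shell:

```bash
smallseg synth-cohort --n-large 18 --n-small 15 --n-normal 15 --n-hyper 7 \
    --seed 0 --out raw/
smallseg preprocess-chgh --in raw/ --out canonical/
```

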