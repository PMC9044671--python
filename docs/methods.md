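# Methods

## Scope and model

`bollseg` estimates seed-cotton yield from low-altitude UAV images of
defoliated, densely planted cotton in three steps: per-pixel boll/background
segmentation with an encoder–decoder convolutional network, computation of
the boll pixel ratio (boll pixels over total pixels), and a linear
calibration from that ratio to plot yield, aggregated to field level by
five-point sampling and converted to kg/ha.

### Segmentation networks

All models are symmetric five-stage encoder–decoders. An encoder stage is a
stack of 3×3 convolutions (each followed by batch normalization and ReLU)
and a 2×2 max-pool that records its argmax indices; the mirrored decoder
stage max-unpools with exactly those indices and convolves. The final
decoder convolution scores `num_classes` channels (no BN/ReLU) ahead of a
per-pixel softmax. Channel widths double per stage from `base_width`,
capped at 8× (the usual VGG/SegNet convention); defaults are 64 for the
full-scale profile and 16 for the desk-scale profile used in the tests.

The variant family varies two axes — convolutions per stage and dilation:

| variant | convs/stage | dilation |
| --- | --- | --- |
| `model1` | 1 | none |
| `model2` | 1 | r=2 in the two deepest stages |
| `model3` | 2 | none |
| `model4` | 2 | r=2 on the second conv of the two deepest stages |
| `segnet_baseline` | 2,2,3,3,3 | none |

The published figures depicting the four block compositions are not legible
at the block level, so the exact per-stage conv counts and dilation
placement were a genuinely open design choice. The realization above keeps
the two stated axes orthogonal: (`model1`,`model2`) and (`model3`,`model4`)
are exact parameter-count twins differing only by dilation (dilation adds no
weights), and both reduced families are strictly smaller than the baseline.
All of it is configurable through `SegModelSpec`.

A dilated 3×3 convolution with rate r has taps spaced r pixels apart, so
its receptive field is `3 + 2(r−1)` per side (5 at r=2, 7 at r=3). Each
dilated conv is zero-padded by r so spatial resolution is never reduced by
convolution — only the recorded-index pooling changes scale.

The layer stack itself (`bollseg.nn`) is a compact numpy implementation
with hand-written backprop: convolutions are im2col gathers feeding one BLAS
matmul per batch, and the backward pass scatters through the same nine
kernel-tap slices. Gradients are verified against central finite
differences in the unit tests, and the forward convolution against a
`scipy.ndimage` dense-correlation oracle with an explicitly zero-dilated
kernel.

### Training

Adam with learning rate 0.001 and decay coefficients beta1 = 0.9,
beta2 = 0.98. The low beta2 (0.999 is the common choice) is kept
deliberately as the calibrated recipe's value. The loss is unweighted
per-pixel cross-entropy on the softmax scores (an optional foreground class
weight exists but is off by default); no augmentation, no early stopping —
a fixed number of epochs with best-checkpoint selection by pooled test-set
mIoU. Fixing the seed fixes minibatch order and (separately, at
`build_model`) weight initialization, making loss trajectories bit-reproducible
on a given BLAS.

Two profiles: the full-scale recipe is 50 epochs, batch 64, 300×300 tiles
(reflect-padded to a multiple of 32 by the inference wrapper); the
desk-scale profile used throughout the test suite is 64×64 tiles,
`base_width` 16, batch 8, 5–10 epochs, which one CPU core trains in a
couple of minutes.

### Metrics

With cotton as the positive class: `IoU = TP/(TP+FP+FN)`,
precision/CPA `= TP/(TP+FP)`, recall `= TP/(TP+FN)`,
`F1 = 2·CPA·Recall/(CPA+Recall)`, and mIoU is the unweighted mean of the
cotton and background IoUs (two classes). Degenerate denominators return 0
with a warning instead of NaN. Dataset aggregation is exposed in two modes
because they genuinely differ: `pooled` sums confusion counts first (and is
invariant to how pixels are partitioned into images); `per_image_mean`
averages per-image metrics, in which case the reported F1 is *not* the
harmonic mean of the reported precision and recall. `per_image_mean` is the
default reporting mode.

The coefficient of determination is implemented in the form used for
segmentation accuracy audits, `R² = 1 − Σ(tᵢ−cᵢ)² / Σ(tᵢ−c̄)²` with t the
model values and c the measured values (note the denominator centres the
*model* values on the *measured* mean — kept literally as specified; it
equals 1 exactly when t = c). For the yield regression the same form is
applied with t = observed and c = fitted yields; because an OLS fit with
intercept equates the fitted and observed means, this coincides with the
conventional regression R².

### Yield model and units

Mask-level ratios are fractions in [0, 1]; the regression operates on
percent. This scale was chosen because the published calibration
`y = 38.6x + 34` with plot yields around 1000–1500 g is only dimensionally
sensible when x is percent (x = 25 → 999 g); the conversion happens at a
single boundary (`estimate_field` / the field-dataset generator) and the
scale is configurable. The sample plot is 230 cm × 100 cm = 2.3 m²;
`to_kg_per_ha(y_g, area) = y_g/1000 · 10000/area`. Relative field error is
`100·|estimated − measured|/measured` and the reported average is the
unweighted mean of per-field errors. Report rounding is half-up, with two
decimals for sub-1% errors and one decimal otherwise (matching how such
tables are conventionally printed); raw values are always reported
alongside.

The two-dataset workflow is encoded as roles, not code paths: the
regression is fitted on equidistant, hand-harvested plots ("data set 1")
and applied to five-point-sampled fields ("data set 2").

## Synthetic data

The generator emulates a defoliated cotton scene's four ingredients:

* **soil** — a dark warm base with smooth Gaussian-filtered value noise
  (`soil_texture_scale` controls the correlation length);
* **mulch-film glare** — 1–3 bright, cool-tinted, nearly texture-free
  vertical strips covering `film_glare_fraction` of the tile. Glare shares
  *brightness* with cotton but differs in chroma and texture, so a pure
  intensity threshold fails while a learned model can separate the classes;
* **bolls** — irregular bright warm-white blobs (unions of jittered disks
  with radii in `boll_radius_range`) with per-pixel speckle;
* **branch occluders** — thin dark line segments at `branch_density` per
  10⁴ px². Occluders remove boll pixels from both image and mask: the
  ground truth is the *visible* boll area, matching how an orthophoto's
  ratio is measured when lower bolls are obscured.

Blobs are added until the visible boll pixel count reaches
`round(target_ratio·H·W)`; the last blob is trimmed rim-inward so the
achieved ratio is exact to one pixel (the ±0.02 contract holds trivially
and the mean achieved ratio is unbiased). Unreachable targets (occlusion
or `boll_count_range` too tight) raise errors naming the constraint. One
master seed spawns per-scene child seeds, so outputs are bit-reproducible.

Simulated plots draw target ratios uniformly from `ratio_range`
(default 10–40%) and assign
`yield_g = 38.6·ratio_percent + 34 + N(0, noise_sd)`. The default
`noise_sd` = 105 g makes the n = 20 fit's R² ≈ 0.91 under the default ratio
range (analytically: signal SD ≈ 38.6·30/√12 ≈ 334 g, and
105 ≈ 334·√(0.09/0.91)); measured over 200 seeded replicates the mean fit
R² is 0.910.

What the generator does **not** emulate: camera optics, ground-sampling
distance and altitude effects, perspective, inter-plant canopy structure,
within-field spatial correlation of boll density, or realistic colour
distributions. Passing tests therefore demonstrate that the pipeline's
mechanics (shapes, gradients, bookkeeping, arithmetic, learnability of a
separable two-class texture/colour problem) are correct — not that the
published real-field accuracies transfer.

## Numerical and procedural choices

* **Tiling**: the 200-tiles-per-5472×3078-frame convention is not
  achievable with non-overlapping 300 px tiles (that gives 18×10 = 180), so
  three policies are exposed — `exact` (non-overlapping, divisibility
  required), `full-cover` (default; minimal evenly spaced covering origins),
  and `fixed-grid` (e.g. 20×10 reproduces 200 tiles/frame with slight
  overlap). Coordinates are 0-based, origin top-left, (x = column,
  y = row).
* **Splits**: seeded permutation; `|train| = round(fraction·total)`
  half-up, so 4000 at 0.8 gives exactly 3200/800.
* **Mask I/O**: disk masks are {0, 255} single-channel PNGs; any other
  value is rejected listing the offending values. Polygon annotations
  (minimal JSON rings) rasterize by the even-odd rule on pixel centres.
* **Inference padding**: images not divisible by 2⁵ are reflect-padded
  bottom/right and the prediction cropped back.
* **Checkpoint selection** uses the test set (it doubles as validation, one
  set, both roles).
* **Desk-scale benchmark thresholds**: the learnability check (variant 4,
  `base_width` 16, 200 easy 64×64 tiles, 10 epochs) asserts test
  mIoU ≥ 0.90; a seeded calibration run reached 0.949, leaving margin. The
  dilated-vs-undilated comparison on the shared 64-tile/5-epoch benchmark
  uses a 0.05 mIoU tolerance — at that budget all variants are
  undertrained, so the check is a soft "dilation does not hurt", not a
  claim of superiority.
* **Confidence-interval coverage** in the regression-recovery test is
  assessed marginally: over 200 seeded replicates, the true slope must lie
  in its 95% CI in ≥ 90% of replicates, and likewise the intercept
  (measured: 94% and 93.5%).

## Known limitations

* The numpy training stack is single-device and unoptimized beyond BLAS;
  the full-scale recipe (4000 tiles of 300², width 64, 50 epochs) is not
  practical on it — it exists to make the desk-scale family trainable and
  exactly inspectable.
* Real-data segmentation accuracy is out of reach of the synthetic
  benchmark by construction; no claim is made about absolute mIoU on field
  imagery.
* The yield model is a single-predictor linear calibration; occlusion of
  lower-canopy bolls biases high-yield fields low, and multi-feature models
  (plant height, weather, soil) are out of scope.
* Only binary (cotton/background) segmentation is supported end to end,
  although the metric and model code is written for k+1 classes.
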