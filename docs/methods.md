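# Methods

`sorghumnet` estimates the number of grains on a sorghum panicle from a
single smartphone photograph.  Detecting individual grains directly is
unreliable — grains are ~8 px across and heavily occluded — so the package
counts by **density-map regression**: a convolutional network maps a
segmented panicle image patch to a non-negative density field whose
integral is the grain count, and a polynomial calibration maps the
one-side (visible) count to the whole-panicle grain number.

## Ground-truth density maps

Each visible grain is annotated with a single point (LabelMe dialect;
0-based x = column, y = row).  Point coordinates are rescaled to the
network input size (224×224 by default), a unit impulse is placed at each
point's nearest pixel (collisions accumulate, so the count is preserved
exactly), and the impulse grid is convolved with a normalized isotropic
Gaussian, σ = 5 px, truncated at 4σ.  With the **reflect** boundary
(default) the map's integral equals the point count to float precision —
this conservation is the load-bearing property of the whole method and is
enforced by property tests.  A `constant` (zero-padded) boundary mode is
provided for comparison; it loses mass for points within ~4σ of the edge.

Impulses are placed on the target grid after coordinate rescaling (rather
than before image resizing) because that order conserves the count exactly;
geometry-adaptive kernels from the crowd-counting literature are
deliberately not used — one fixed σ matches the near-constant grain scale.

## The counting network

Sorghum-Net is a three-column fully convolutional network.  Columns use
kernel sizes 3/5/7 with four same-padded convolutions each (channel widths
80-160-80-40, 40-80-40-20, 20-40-20-40), batch normalization after every
column convolution, ReLU activations, and a 2×2/stride-2 max pool after
each column's first two convolutions.  The column outputs (40+20+40 = 100
channels at 1/4 resolution) are concatenated, upsampled ×4
(nearest-neighbour by default, bilinear available) and passed through a
1×1 convolution to a 2-channel head with a final ReLU; the density
estimate is head channel 0, and channel 1 is ignored.  At the default
configuration the network holds **568,402 parameters (568K)** counting the
two running statistics of every batch-norm channel —
`count_parameters(handle, include_statistics=True)` reproduces the figure
and is cross-checked in the tests against independent per-layer arithmetic
(k²·c_in·c_out + c_out per convolution, 4 values per BN channel).

The network is implemented directly on NumPy (NHWC, im2col convolution
through BLAS matmuls, hand-derived backward passes, Adam).  This keeps the
package dependency-light and bit-deterministic under a fixed seed and
single-threaded BLAS; every backward pass is validated against central
finite differences in the test suite.  `float32` mode halves memory
traffic and roughly doubles CPU throughput; counting accuracy is
unaffected.

Numerical choices that are not visible in the architecture description:

- **Padding** is `same` everywhere (output-size arithmetic requires it).
- **Input normalization**: pixels scaled to [0, 1].
- **Initialization**: He (variance-scaling) normal, seeded.
- **Batch-norm momentum 0.9, eps 1e-3.**  Momentum 0.9 lets the running
  mean/variance converge within a few hundred optimizer steps, so
  eval-mode predictions are calibrated even in short CPU schedules; with
  slower-moving statistics (e.g. 0.99), short runs exhibit a large
  train/eval gap and early stopping selects on a miscalibrated
  validation loss.
- **`output_scale`** (default 1): the network regresses
  `density × output_scale` and predictions are divided back.  Per-pixel
  densities peak at 1/(2πσ²) ≈ 0.0064, and regressing such small targets
  conditions the optimization poorly at short schedules; scaling them into
  an O(1) range (`output_scale = 100`) stabilizes training without
  changing the counting semantics.
- **Max-pool ties** propagate gradient to every maximal element (a
  measure-zero event for real-valued activations).

## Training

Adam (lr 0.001), batch size 8, pixel-mean MSE between head channel 0 and
the ground-truth map, at most 200 epochs with early stopping after 20
epochs without validation improvement (min-delta 0) and restoration of the
best weights.  The mean (not sum) over pixels is used in the loss; this is
documented because it changes the effective learning rate relative to a
sum-reduction implementation.  Data order is reshuffled every epoch from
the run seed; training is deterministic given the seed.  Validation data
is carved from the training side (the protocol defines only an 80:20
train/test split).

Count accuracy is summarized by MAE, MSE, MAPE (0–100% scale, observed
values must be positive) and RMSE = √MSE, computed per image by comparing
the integral of the predicted map with the annotated count.

## Augmentation

Each source image yields `variants_per_image` augmented copies (default
40, which expands 120 patch images to 4,800; originals are not kept).
Photometric ops — hue/saturation shift, Gaussian noise, blur, channel
inversion, contrast, additive value — touch pixels only.  Geometric ops —
rotation within ±25° about the image centre, horizontal/vertical flips —
are applied through one explicit affine transform to pixels, mask and
point coordinates alike; points leaving the frame are dropped.  Density
maps are **regenerated from the transformed points** rather than warped as
images, because image-space interpolation does not conserve mass.  Per-op
probabilities and magnitudes are package defaults (the protocol lists the
op types only).

`split_dataset` partitions at `source` level by default, keeping all
augmented variants of one source image on the same side of the train/test
boundary (no augmented-twin leakage); `record` level reproduces the
simpler protocol of shuffling individual images.

## Whole-panicle estimation

One photo shows one panicle face.  The pipeline per side: zero the
background with the (manual) segmentation mask, cut the masked image into
three equal-height patches — ⌊H/3⌋, ⌊H/3⌋, with the remainder of H mod 3
on the bottom patch, so the patches always tile the image exactly — resize
each patch to the network input, predict and integrate a density map per
patch, and sum the three patch counts into `total_visible`.  A polynomial
(degree 2 by default; the degree is a config knob, as only the curvature
of the published calibration plot hints at it) is fitted by least squares
with the machine-counted whole-panicle total as response and the one-side
estimate as predictor, on a random 70:30 train:test split; held-out R²,
MSE, RMSE and MAPE are attached to the fitted model.  Predictions are
clipped below at zero.  A symmetry report computes MAE/MSE/RMSE between
the side-A and side-B visible-count estimates of the same panicles.

## Synthetic benchmark

The field dataset is not publicly deposited, so the package ships a
generator that emulates its geometry: a tapered-ellipse panicle silhouette
on a cluttered background, filled with anti-aliased elliptical grain blobs
(diameter 8 px ± 25%, colour-jittered) at Poisson-disk-like positions
strictly inside the mask.  Background distractors never touch the mask, so
the visible ground truth is exact by construction.  Whole-panicle totals
follow a truncated normal over the observed field range 672–4,156 grains
with mean 2,363 (σ = 700, a package choice — no distribution is reported);
the per-side visible count inverts a quadratic visibility relation
`total = a·v² + b·v + c` (defaults a = 1e-4, b = 2, c = 0, i.e. roughly
half the grains visible per side, with a small curvature) plus 5% relative
noise, and opposite sides spread around the shared total with a relative
asymmetry σ (default 5%).  The relation is a parameterized stand-in for
testing, not a biological claim.

What passing tests on this benchmark do show: the density pipeline
conserves counts, the network can learn to count blob-like objects from
masked imagery, and the calibration recovers a known visibility relation.
What they do not show: robustness to real field conditions — occlusion by
awns and rachis branches, specular highlights, defocus, mislabelled
points — none of which the generator models.

## Scaled-down acceptance run

The end-to-end training check runs at desk scale on one CPU: 30 synthetic
panicle pairs (60 scenes → 180 patches), source-level 80:20 split, one
augmented variant per training image, 112×112 inputs, column widths scaled
by 1/8 (≈9.6K parameters), float32, `output_scale` 100, Adam lr 0.003,
batch 8, at most 25 epochs with patience 8.  The width, input size and
learning rate are scaled-run adaptations chosen from a compute budget (the
full-width network at full resolution needs on the order of 10⁵ GFLOPs per
epoch-equivalent schedule) — the published training recipe (lr 0.001, 200
epochs, patience 20, batch 8, 224×224) remains the package default.  The
run must reach held-out per-patch MAPE ≤ 35%.

## Known limitations

- The NumPy engine targets correctness and determinism, not speed;
  full-width training at 224×224 is impractical on a single CPU.
- The generator's visibility relation and asymmetry are assumptions; the
  calibration stage should be refitted for any real dataset.
- MAPE is undefined for images with zero observed grains; such records
  must be excluded or evaluated with MAE/RMSE only.
- Two-channel head: channel 1 is trained against nothing and ignored, as
  the printed architecture specifies a 2-channel head.
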