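# Methods

`vetgan` implements a two-fold screening pipeline for binary
healthy/unhealthy animal image classification: (1) image preparation —
resizing, backdrop substitution, fuzzy-inference brightness correction and
combinatorial offline augmentation — and (2) a semi-supervised generative
adversarial network (SGAN) whose discriminator doubles as the classifier.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Fuzzy brightness correction

Pixel intensity on `[0, 255]` is treated as a linguistic variable with
five terms. Membership functions (MFs) are trapezoids on the shoulders
and gaussians in the interior:

| term        | shape     | parameters            |
|-------------|-----------|-----------------------|
| Very Dark   | trapezoid | (0, 0, 32, 64)        |
| Dark        | gaussian  | mean 80, sigma 25     |
| Medium      | gaussian  | mean 128, sigma 25    |
| Bright      | gaussian  | mean 176, sigma 16    |
| Very Bright | trapezoid | (191, 223, 255, 255)  |

Five single-antecedent rules map input terms to output terms on a signed
adjustment universe `[-delta_max, +delta_max]` (default `delta_max = 64`),
with symmetric triangular output MFs centered at -48, -16, 0, +16, +48
(half-width 16):

    Very Dark   -> Slightly Dark        Dark   -> Very Dark
    Medium      -> Slightly Bright      Bright -> Slightly Bright
    Very Bright -> No Change

Inference is standard Mamdani: min implication (for single-antecedent
rules the firing strength is the membership degree itself), max
aggregation across rules sharing a consequent, and centroid
defuzzification of the clipped, aggregated output set, evaluated
numerically on a 2049-point grid. When nothing fires the adjustment is
defined as 0 — the safe degenerate behaviour for an enhancement filter.

Because the input universe is discrete, the full inference chain is
evaluated once per intensity into a 256-entry lookup table (LUT); a
tested property guarantees the LUT equals the unfolded per-pixel
pipeline. LUT deltas are quantized to integers: 8-bit pixel updates round
anyway, so quantization is lossless, and it makes the No-Change rule hold
exactly on the Very Bright plateau `[223, 255]`. That exactness also
motivates Bright's tighter sigma (16 vs. 25): with a wider gaussian,
Bright's tail still fires Slightly Bright at intensity 223+ and saturated
pixels would never be left strictly unchanged.

By default the correction is applied to the value channel of an HSV
decomposition (`channel_mode="luminance"`), which preserves hue; a
`per_channel` mode shifts each RGB channel independently through the same
LUT.

Enhancement fidelity is measured by the peak signal-to-noise ratio
`PSNR = 10 log10(G^2 / MSE)` with `G = 255`, where the MSE averages the
squared difference over all pixels and channels. (Some texts label this
divisor RMSE; it is a mean of squares and is implemented as such.)
Identical images report an infinite PSNR sentinel. Thin wrappers around
CLAHE and classic histogram equalization are provided for comparison.

## Offline augmentation

Five transform kinds: horizontal flip, vertical flip, rotation (angles
0-358 degrees on a 2-degree grid), scale-up (factors 1.0-2.0, step 0.1)
and scale-down (factors 1.0-0.5, step 0.1). A plan is a subset of one to
four distinct kinds; subsets containing both scale kinds are excluded
because the pair collapses to whichever factor dominates. Of the 30
subsets of size 1-4 this leaves exactly 23. Factor 1.0 stays on both
scale grids even though it is an identity — the grids are implemented
verbatim.

Within a plan, ops apply in a fixed canonical order (flips, rotation,
scaling) so a manifest row fully determines the output. Rotation fills
exposed corners with white, consistent with the white backdrop; right
angles are computed exactly by array rotation, other angles by bilinear
resampling. Scaled images are mapped back to the working canvas —
center crop after scale-up, centered white padding after scale-down — so
every output keeps the working resolution. One seeded RNG drives all
sampling; the augmentation manifest records source, ops, parameters and
seed, making a rerun byte-identical.

## Semi-supervised GAN

**Discriminator.** A residual convolutional backbone (3x3 stem, then
stages of two-conv residual blocks with projection shortcuts; the
production configuration is the classic 18-layer arrangement of
(2,2,2,2) blocks over (64,128,256,512) channels) feeds a global average
pool, a fully connected *interpretation layer* of configurable width
(ReLU), and a `K+1`-way softmax: `K = 2` real classes plus one class for
generated images. The interpretation layer's activations are the feature
map `f(x)` used by the generator objective; its width can be tuned by a
linear search that trains one short-budget model per candidate and keeps
the width with the best validation accuracy (ties to the smaller width).
Pretrained backbone weights are not bundled; the discriminator trains
from random initialization.

**Generator.** A latent normal vector (`latent_dim`, default 100) is
projected to a `side/16 x side/16` seed map and passed through five
convolutional layers: four stride-2 transposed convolutions (kernel 4,
batch norm, ReLU) that double the spatial size to `side`, then a stride-1
3x3 convolution with tanh output in `[-1, 1]`. Images map to the tanh
range by `x/127.5 - 1`, a round trip that recovers 8-bit inputs exactly.

**Losses.** With `p_D(y|x)` the K+1 softmax and class `K+1` meaning
"generated":

* supervised (labeled reals): `-E log p_D(y | x, y < K+1)` — the softmax
  restricted and renormalized to the K real classes;
* unsupervised, real term (unlabeled reals): `-E log(1 - p_D(K+1 | x))`;
* unsupervised, fake term (generated): `-E log p_D(K+1 | G(z))` by
  default. A `log_free_fake_term` flag switches to the log-free variant
  `-E p_D(K+1 | G(z))`; it is not a log-likelihood and trains less
  stably, so the log form is the default;
* generator (feature matching): `|| E f(x) - E f(G(z)) ||_2^2` over
  batch means.

The logged discriminator loss is the sum of its supervised and
unsupervised parts at every epoch, a tested invariant. All gradients are
derived analytically and checked against finite differences.

**Training schedule.** Each epoch runs three phases in order: (i)
unsupervised discriminator steps over the shuffled unlabeled pool, each
paired with a fresh generated batch; (ii) supervised steps that resample
the labeled subset for as many minibatches as phase (i) ran — with a
10% labeled fraction a single labeled pass would contribute ~1 step
against ~9 unsupervised steps per epoch and the classifier head starves;
(iii) feature-matching generator steps (by default one per two
unsupervised batches). Optimization is Adam (learning rate 2e-4
production default, betas (0.5, 0.999)); both networks run in float32 on
a hand-rolled numpy layer stack (`vetgan.nn`) with im2col convolutions.
Two optional regularizers are exposed in the config: a weight on the
unsupervised gradient (`unsup_weight`, default 1.0 — down-weighting to
0.5 damps adversarial feature drift in low-label regimes) and a step
learning-rate decay (`lr_decay_every`/`lr_decay_factor`, off by
default); `warmup_epochs` (default 0) runs supervised-only epochs before
the adversarial phases start, and `generator_lr` decouples the
generator's learning rate. The logged losses are always the unweighted
values, so the discriminator-loss additivity holds regardless.

One detail is not optional: during discriminator passes over *generated*
batches, batch-norm layers normalize with the batch statistics as usual
but do not fold them into their running averages. Inference is always on
real images, so the running statistics must describe real data; early in
training (or whenever the generator diverges) fake-batch statistics sit
arbitrarily far from the real-image distribution, and letting them into
the running averages was observed to collapse eval-mode accuracy to
chance on some seeds while train-mode losses looked healthy.

**Early stopping.** Training is capped at `max_epochs` (default 100) and
stops when the monitored validation quantity fails to improve by more
than `min_delta = 1e-4` for `patience` (default 10) consecutive epochs;
the best-validation checkpoint — weights *and* batch-norm running
statistics — is restored. The monitored quantity is the validation
error rate, not the validation supervised loss: under adversarial
feature drift the supervised loss on held-out data rises through
miscalibration alone while classification keeps improving, and
loss-based stopping was observed to freeze checkpoints at epoch 1-2.

**Supervised-only control.** The same discriminator architecture trained
with only the supervised loss on the same labeled subset, same optimizer,
schedule and early stopping — the reference against which the
semi-supervised advantage is measured.

## Synthetic data

Real photographs of healthy and diseased animals cannot ship with the
package, so a generator produces the structure the pipeline relies on: a
bright, mildly textured ellipse ("body") on a black backdrop, with the
unhealthy class adding 2-4 dark circular blobs (radius 2-4 px at the
32 px test scale) inside the body — a stand-in for the localized
skin-lesion phenotype. Per-image base brightness is drawn from a wide
range (default 40-220) so the fuzzy enhancement is exercised across all
five linguistic regimes, and the black backdrop keeps the
background-substitution step observably active. Class counts are exact,
the labeled subset is stratified, and everything reproduces from one
seed.

What it deliberately does not model: photorealistic texture, pose and
viewpoint variation, inter-class appearance overlap, or label noise.
Classes are separable by construction (a lesion-presence oracle is
exported), so passing benchmarks demonstrates that the training
machinery extracts the available signal at desk scale — not that the
method reaches any particular accuracy on real animal photographs.

## Benchmark and problem sizes

The packaged benchmark (`sgan.run_synthetic_benchmark`) trains on 600
synthetic 32x32 images with 10% labeled (60 labeled / 540 unlabeled),
early-stops against a separately generated 100-image labeled validation
set, and reports accuracy on a held-out 200-image test set, for both the
SGAN and the supervised-only control. The labeled fraction applies to
the training pool; validation and test sets are additional draws from
the same population. The 60 labeled originals are expanded with two
offline geometric augmentations each (the pipeline's standard
anti-overfitting step): without it the discriminator drives its training
loss on the labeled originals to zero within a few epochs and, on
unlucky seeds, never generalizes past chance. Both models receive the
identical augmented labeled set, so the SGAN-vs-control comparison still
isolates the contribution of the unlabeled pool. The desk-scale network is a narrower, shallower
instance of the production family: stages (12, 24, 48) with one block
each and a stride-2 stem, generator channels (64, 32, 24, 16, 12),
latent 64, interpretation width 64, batch 64, learning rate 1e-3
halved every 10 epochs, unsupervised-gradient weight 0.5, at most 35
epochs with patience 12. Across seeds this configuration's median
held-out accuracy clears 0.85 and beats the supervised-only control by
a wide margin; one full benchmark (SGAN + control) takes a few minutes
on one CPU core.

## Numerical choices and degenerate inputs

* Centroid defuzzification on a 2049-point grid; zero-area aggregate
  returns delta 0.
* LUT deltas quantized to integers (lossless for 8-bit pixels).
* Background substitution requires *all three* channels below the
  threshold (default 10) — a conservative rule that spares dark fur.
* Images with conflicting COCO labels raise an error (no majority vote);
  unannotated images are skipped with a warning.
* Zero-denominator evaluation metrics return 0 with a logged warning so
  sweeps never abort; AUC uses tie-averaged ranks (Mann-Whitney).
* Batch norm needs at least two samples; trailing one-image minibatches
  are dropped.
* Width-search ties resolve toward the smaller (cheaper) width.
* A single root seed derives one named substream per pipeline stage, so
  stage outputs are pure functions of (inputs, config, seed).

## Known limitations

* CPU-only numpy networks: production-scale 256x256 training with the
  full 18-layer backbone is architecturally supported but impractically
  slow without an accelerator.
* No pretrained discriminator weights; `pretrained=True` raises.
* The log-free literal fake-term variant is provided for completeness
  but destabilizes training and is off by default.
* Adversarial training at this scale retains seed-to-seed variance:
  across many seeds most benchmark runs land near or above 0.9 held-out
  accuracy, but occasional seeds converge several points lower. The
  packaged benchmark therefore reports a median over seeds.
* The synthetic benchmark bounds what the tests can claim about real
  data (see above); PSNR values on synthetic images are not comparable
  to values reported for photographic datasets.
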