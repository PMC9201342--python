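# Methods

## Problem setting

A segmentation network `f_s` is trained on a labeled *source* domain.  At
deployment the data distribution has shifted (different tumor-subtype
population, different MR contrast), and `f_s` is available only as a
black-box API: images in, per-pixel softmax histograms out.  No source
images, labels, parameters, or gradients are available.  The goal is to
train a *target* network `f_t` — possibly with a different backbone — on
unlabeled target images so that it outperforms direct application of the
source model.

## Objective

Adaptation minimizes, per batch of target images,

```
L = L_KL + alpha(I) * L_Ent
```

* **EMD pseudo label.**  `y' = lambda * f_s(x_t) + (1 - lambda) * f_t(x_t)`
  per pixel, with `lambda(I) = lambda0 * exp(-gamma * I)`, `lambda0 = 1`.
  The pseudo label is a constant (stop-gradient) during backprop: this is a
  self-training construction, and letting gradients flow through both KL
  arguments would change the objective.  A flag disables the stop-gradient
  for study.
* **Distillation.**  `L_KL` is the mean over all pixels of all images in the
  batch of `D_KL(f_t(x_t)_n || y'_n)` — the forward direction, target
  prediction first.  The reverse direction is available behind a flag, off
  by default.
* **Entropy minimization.**  `L_Ent` is the mean per-pixel Shannon entropy
  of `f_t(x_t)`; its weight decays linearly, `alpha(I) = alpha0 * (1 - I/E)`
  with `alpha0 = 5`, reaching exactly 0 at the final epoch.  `constant` and
  `zero` modes support the ablations.
* **Source cross-entropy.**  Source training minimizes pixel-wise CE written
  with a `1/C` factor inside the class sum; the factor rescales the loss
  without moving its argmin, and a flag restores conventional CE (the target
  warm-up uses the conventional scaling).

Numerics: probabilities are clamped to `[1e-8, 1]` and renormalized before
any logarithm; softmax lives inside the networks so every loss consumes
valid distributions.

## Decay units at desk scale

The decay index `I` counts epochs, not mini-batch iterations — counting raw
iterations would extinguish `lambda` within a handful of batches.  The rate
`gamma` is config-exposed because the meaningful quantity is *how much
distillation happens before the teacher anchor fades*, which is proportional
to images-per-epoch.  A full-scale run sees tens of thousands of slices per
epoch; a desk-scale run sees a few dozen.  The benchmark therefore sets
`gamma = 5/E` so that `lambda` traverses 1 -> ~0.007 over its own horizon
`E`, preserving the qualitative schedule (source weight large early, near
zero late).  With the default `gamma = 1` at desk scale the anchor vanishes
after ~3 epochs and self-training collapses to the majority class — an
instructive failure mode, reproducible by setting `lambda_decay_rate=1`.

## Networks

Both backbones are skip-connected encoder-decoders (U-Net family) built on
a small NumPy engine written for this package: im2col convolutions,
batch normalization, 2x2 max-pooling, nearest-neighbor-upsampling decoders,
softmax head, Adam.  Every layer's backward pass is exact and checked
against central finite differences in the test suite.  Depth `d` gives
`4d + 3` convolutional layers; the `full_scale_config()` preset (depth 3,
width 16) realizes the classic 15-conv-layer layout for 128x128 inputs,
while tests and the benchmark use depth 2 / width 8 at 64x64.  The
`separable` style replaces each 3x3 convolution with depthwise + pointwise
convolutions (MobileNet family), cutting parameters several-fold at equal
width/depth; it serves as the different-backbone target in the
cross-backbone arm.

Target initialization is from scratch (the black-box contract forbids
copying source weights), followed by a short warm-up: the fresh student is
trained with CE on the argmax of the black box's predictions so that
`f_t(x_t)` is non-degenerate when it enters the EMD mixup.  Warm-up length
is config-exposed; 0 disables it.

## Synthetic phantoms

The generator emulates multi-modal brain-tumor slices: nested elliptical
regions (class 1 core, class 2 enhancing ring, class 3 edema ring; WholeT =
union) on a textured background, rendered to `C_ch` channels through a
fixed class-by-channel base-intensity table.  Intensities of all classes,
background included, overlap across channels, so no single brightness
threshold segments the image — the segmenter must combine channel
contrasts, as with real MR modalities.  Rendering applies, in order: gamma
nonlinearity, gain/offset, channel mixing, Gaussian blur, additive Gaussian
noise.  All outputs are pure functions of (spec, params, seed).

Two shift regimes mirror the standard UDA protocols:

* **cross-subtype** (default benchmark): target tumors drawn at 0.6x the
  source radii plus a moderate appearance shift (gamma 1.5, gain 0.85,
  offset 0.08, blur 1.0 px, noise 0.07).  Chosen so that a well-trained
  source model remains *confident but imperfect* on target data — the
  regime the adaptation method addresses; much harsher shifts make the
  teacher so uncertain that distilling it is pointless, much milder ones
  leave no headroom.
* **cross-modality**: single-channel images; the target applies a monotone
  nonlinearity with inverted contrast (`1 - base^1.5`), T1-vs-T2-like.

What the phantoms do **not** model: anatomy outside the lesion, partial
volume and bias fields, 3-D continuity across slices, scanner-specific
noise spectra, inter-rater label noise.  Passing directional tests on
phantoms shows the adaptation machinery behaves as designed under a
controlled shift, not that specific DSC/HD levels transfer to clinical data.

## Desk-scale benchmark protocol

One benchmark seed: generate 32 labeled source / 40 unlabeled target
training images (64x64, 4 channels), 6 target-val, 16 target-test; train
the source net 50 epochs (Adam, lr 1e-3, betas 0.9/0.99, batch 8; 20% of
the source split held out for best-checkpoint selection); seal it; then run
the arms.  Target training uses dihedral (rotation/flip) augmentation of
image + pseudo-label pairs — standard segmentation practice that lets the
student generalize past its teacher's per-image noise.  Warm-up runs 50
epochs at lr 1e-3 with the best-validation epoch retained, bringing the
student to convergence *before* the EMD phase: entropy minimization
sharpens boundaries on a confident student but collapses a soft one toward
the majority (background) class, so the order matters.  The EMD phase then
runs 12 epochs at lr 1.5e-4 with `gamma = 5/12`.  A small labeled
target-val split selects the best epoch in each phase (the adaptation
losses themselves never see target labels), mirroring standard UDA practice
of tuning on a tiny validation set.

Problem sizes were chosen so the three-seed benchmark runs in minutes on a
single CPU; the comparisons are directional analogues of the full-scale
study (source-only vs. adapted, with/without entropy, cross-backbone), not
reproductions of its absolute numbers.

## Metrics

* **DSC** `2|A∩B| / (|A|+|B|)`; both-empty pairs score 1, exactly-one-empty
  0.
* **Hausdorff** on boundary pixels (mask pixels with a background
  4-neighbor; the image border counts as background), Euclidean distances on
  the pixel grid times `spacing`.  Two variants are kept because the two
  common definitions disagree: `max` (classical max of directed maxima, the
  default in reports) and `average` (mean of the two directed mean
  distances).  Both-empty pairs score 0; one-empty pairs are undefined and
  excluded from means with the exclusion counted.  Reported HD is 2-D
  per-slice.
* Regions: CoreT (class 1), EnhT (2), ED (3), WholeT (union).

## Known limitations

* The engine is CPU-only and sized for small images; it is a faithful but
  slow stand-alone implementation, not a general DL framework.
* The adaptation gain at desk scale leans on best-val-epoch selection and
  augmentation; with neither, prolonged soft distillation against an
  uncertain teacher can erode a good student (mode-seeking forward KL
  sharpens toward the majority class).
* BraTS-style NIfTI input is supported (z-score over nonzero voxels per
  volume; labels remapped to contiguous ids) but untested against real
  BraTS conventions beyond synthetic round trips; the normalization choice
  is a stand-in since the reference pipeline's is unspecified.
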