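# Methods

## Model

A *weak classifier* is a convolutional feature extractor `f : R^{H×W×3} →
R^d` — a CNN up to and including global average pooling — composed with an
affine head `h(z) = Wz + b`, `W ∈ R^{C×d}`, and a log-softmax over the `C`
classes. The *minimal ensemble* takes exactly two trained weak classifiers,
drops both heads, freezes both extractors, and trains a single fusion layer

```
g(x) = log_softmax( W_f [f_1(x); f_2(x)] + b_f ),   W_f ∈ R^{C×(d_1+d_2)}
```

The fusion is deliberately just an affine map — an adaptive weighted sum of
the concatenated deep features. Keeping the weak models' own heads as well
would duplicate the role of this layer, so they are removed rather than
stacked. The trainable-parameter count of the ensemble phase is therefore
exactly `(d_1+d_2)·C + C`; for two EfficientNet-b0 extractors (`d = 1280`)
and 39 classes, 99,879.

The truncation point is immediately after global average pooling: that is the
only cut that yields a flat per-example vector the affine fusion can consume
directly, and it matches the usual notion of a CNN's "deep features".
Concatenation order is the selection rank order (best model first) and is
recorded in checkpoint metadata, since the fusion is order-covariant.

## Training protocol

All phases share one early-stopping loop:

* batch size 32, last partial batch kept (no batch-level stratification —
  with more classes than the batch size it would be impossible anyway);
* after every epoch, weighted F1 on the full validation split;
* a *strict* increase marks a new best epoch; ties do not reset patience;
* stop after `patience = 10` epochs without improvement, or at
  `max_epochs = 100` (a safety cap; patience is the operative criterion);
* the returned model is the best-epoch state (parameters and batch-norm
  running statistics are snapshotted and restored).

Phase settings:

| phase | trainable set | optimizer | regularization |
|---|---|---|---|
| end-to-end | all parameters | AdaBelief lr 5e-4, betas (0.9, 0.999), eps 1e-16, decoupled weight decay, no rectification | none |
| head fine-tune | head only | SGD lr 3e-3, momentum 0.9 | L1 or L2, λ ∈ {0, 1e-4, 5e-4, 1e-3}, head parameters only |
| ensemble fine-tune | fusion only | AdaBelief (as above) | none |

One seed drives model initialization, the stratified split, and the shuffle
order of its run. Because every run draws its own split, independently seeded
weak models train on different random subsets (bagging); consequently a weak
model's training items can appear in a later ensemble run's test split. The
grid runner logs this overlap fraction per run rather than hiding it — the
per-seed-split scheme is part of the protocol, and its cross-validation-like
averaging is the intended reading.

When the feature stack below the trainable set is frozen, the loop
precomputes the features once (in inference mode) and trains the affine part
on the cache. This is an exact optimization, not an approximation: a frozen
extractor in inference mode is a fixed function of its input, so the training
trajectory is identical to recomputing features every batch.

Weak-model selection ranks candidates by *validation* weighted F1 (descending),
breaking ties by lower seed and then run order. Validation rather than test
score is used so the test split never influences model choice.

## Metrics

Weighted F1 is the support-weighted mean of per-class F1. Per-class F1 is 0
when precision + recall = 0; classes absent from the reference labels have
zero support and drop out of the weighting. This matches the dominant
convention (verified against scikit-learn to 1e-9 in the tests, which keep
the reference implementation strictly as an oracle). Accuracy is used on the
test split for comparability with prior work. Scores live in [0, 1] inside
the library; the CLI prints percentages with 4 decimals. Argmax prediction
ties resolve to the lowest class index.

## Numerical core

The package carries its own NumPy layer stack: im2col convolutions (standard
and depthwise), batch normalization (train/eval modes, running statistics as
buffers excluded from parameter counts), SiLU/ReLU, non-overlapping max
pooling, squeeze-excitation, MBConv inverted-bottleneck blocks with residual
connections, linear and log-softmax layers — each with an explicit backward
pass, validated against central finite differences in the test suite. The
EfficientNet b0–b7 family is built from these blocks with the standard
compound-scaling widths/depths and divisible-by-8 channel rounding; the
resulting totals reproduce the published counts exactly (b0 = 5,288,548 with
a 1000-class head; b7 = 66,347,960). Dropout and stochastic depth are
omitted: they carry no parameters, and the desk-scale backbone does not need
them. Optimizers (AdaBelief with decoupled weight decay and no rectification;
SGD with classical momentum) are implemented from their published update
rules and unit-tested against closed-form single steps.

ImageNet-pretrained initialization is expressed as a flag plus a local
weights-file registry; without a registered weights source, requesting
pretrained initialization raises an explicit error rather than silently
falling back to random weights. All experiments in the test suite use seeded
random initialization.

Everything is float64. Given a seed, builds, splits, shuffles and training
histories are bit-reproducible; checkpoints round-trip exactly (npz weights +
JSON metadata side-car recording backbone id(s), class list, normalization
stats, seed and phase).

## Data handling

* Class order is the lexicographic order of directory names; it fixes label
  indices everywhere.
* Stratified splitting uses per-class largest-remainder (Hamilton)
  allocation; leftover items go to the split with the largest fractional
  remainder, ties to the earlier split (train, valid, test). Per class and
  split the realized count differs from the exact proportion by less than 1.
* Normalization statistics are the per-channel mean and *population* SD of
  [0, 1]-rescaled intensities pooled over all pixels, computed in two passes
  for numerical stability. They are computed over the whole dataset by
  default, matching the single per-dataset constants the protocol uses; this
  leaks marginal pixel statistics across splits, so a `subset` argument
  exposes the train-only alternative.
* Preprocessing is a direct square resize (bilinear by default, no
  aspect-preserving crop — the targeted datasets are square) followed by
  `(x − μ)/σ`. Non-RGB input is rejected rather than silently converted.
  A zero-SD channel is accepted only for data constant at the mean.

## Synthetic data

The generator writes image-folder trees whose classes differ along three
independent factors: base hue (evenly spaced on the color wheel), sinusoidal
texture frequency, and the number of bright Gaussian blobs. Per-image
perturbations — hue jitter, blob placement and size, pixel noise — are scaled
by `(1 − difficulty)`, so `difficulty` acts as a separation dial: at 0.9 a
small CNN separates the classes almost perfectly, at 0.3 it cannot. Three
independent factors give two weak models trained on different subsets a
chance to rely on partially different features, which is what leaves the
feature-fusion ensemble headroom. Defaults (5 classes, 40 images per class,
64×64 px, difficulty 0.9) define the desk-scale experiment the acceptance
script runs; uneven per-class counts are supported to exercise the
support-weighting path of the F1 metric. PNG output keeps regeneration
byte-identical across platforms.

What the synthetic data does *not* emulate: photographic texture, intra-class
pose/lighting variation, background clutter, and the fine-grained inter-class
similarity of real leaf-disease imagery. Passing the desk-scale suite
therefore demonstrates the correctness of the pipeline mechanics (splitting,
protocols, freezing, fusion, selection, metrics), not field performance on
real crops.

A separate feature-level fixture draws class-conditional Gaussians with unit
within-class SD and configurable mean separation (pairwise mean distance =
`separation` within each feature block), for testing the fusion layer in
isolation: at separation ≥ 4 SDs the classes are linearly separable with
overwhelming probability, at 0 they are indistinguishable.

## Problem sizes and limitations

The bundled experiments use the `tiny` backbone (three conv-BN-ReLU stages,
`d = 64`, ~24k parameters) on 64×64 synthetic images with 200-image datasets
and an 80/10/10 split — sizes chosen so a full two-weak + ensemble campaign
completes in a few minutes on one CPU. At this scale validation splits are
small (20 items), so validation weighted F1 saturates within a few epochs and
early stopping can return a very early state; occasional weak-model test
scores around 0.9–0.95 (one or two errors on 20 test items) are ordinary
seed-to-seed variation, and the fused ensemble is markedly more stable than
either weak model. EfficientNet variants are fully constructible and runnable
forward (b0 at 256×256 takes a few seconds per image on one CPU), but
training them end-to-end in NumPy at full dataset scale is outside the
intended use; the full-family grid is exposed primarily as a planner plus the
exact parameter accounting.
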