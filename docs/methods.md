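# Methods

## Problem and model

The package classifies aerial image chips of individual *Miscanthus* plants
as having visible panicles ("heading", class 1) or not (class 0), with as
few human-annotated chips as possible. The core method is a semi-supervised
GAN: a generator G maps a latent vector z ~ N(0, I) to a fake chip, and a
discriminator D carries **two heads over one shared backbone**:

- a supervised head producing 2-class softmax probabilities
  p(y | x, y < K+1) from logits l(x);
- an unsupervised real/fake head computed **from the same logits** by the
  normalised-sum-of-exponentials activation

      D(x) = Z / (Z + 1),   Z = Σ_k exp(l_k(x)),

  evaluated stably as sigmoid(logsumexp(l)). A generated image plays the
  implicit K+1-th class, with p(y = K+1 | x) = 1 − D(x).

Because the unsupervised head is literally a deterministic function of the
supervised head's logits, the two classifiers share every parameter, and an
update through either objective moves both — this coupling is what lets
thousands of unlabeled chips shape the representation that the few labeled
chips then calibrate.

Losses (ε = 1e-7 floors every log):

- supervised: mean −log p(y | x, y < K+1) over the labeled half-batch;
- unsupervised: −E log D(x_u) over real unlabeled chips plus
  −E log(1 − D(G(z))) over fakes;
- generator: feature matching, ‖mean f(x_u) − mean f(G(z))‖² over
  post-flatten, pre-dropout backbone features. The training loop's wording
  ("extract features and calculate G loss") admits more than one reading, so
  a non-saturating adversarial generator loss is available behind
  `TrainConfig.generator_loss="non_saturating"`; feature matching is the
  default because it is the standard choice for semi-supervised GAN
  classifiers and is markedly more stable at these batch sizes.

Each training step executes, in order: (1a) supervised D update on the
labeled half-batch; (1b) unsupervised D update on real unlabeled chips;
(1c) unsupervised D update on freshly generated fakes; (2) one G update
with D frozen. Freezing is enforced by simply not stepping the frozen
submodel's optimiser; gradients may flow through it but its parameters are
bit-identical before and after the phase (tested by hashing).

## Architectures

All tensors are channels-last float32. The engine (`phenogan.nn`) is a
small NumPy layer library with explicit backward passes (im2col
convolutions, per-offset scatter for the transposed convolution and the
convolution backward), written for this package and verified against
finite differences.

**Generator**: Dense(latent 100 → (S/4)²·128), LeakyReLU(0.2), reshape,
ConvTranspose(128→64, 3×3, stride 2), LeakyReLU, ConvTranspose(64→3),
Tanh; output S×S×3 in [−1, 1] (S = 72 by default).

**Discriminator**: 4 × [Conv 3×3 (widths 32, 64, 128, 128), LeakyReLU(0.2),
max-pool 2], flatten, 40% dropout, dense 2-class head. Latent dimension
(100), channel widths and the LeakyReLU slope are free constants chosen to
keep the parameter count near the custom CNN's.

**Custom CNN**: 6 × [Conv 3×3 (widths 32, 32, 64, 64, 128, 128), batch
norm, ReLU, max-pool 2], 40% dropout after stages 2, 4, 6, flatten, dense
128 + batch norm + ReLU + 50% dropout, sigmoid scalar. The dense width
(128) is a free constant. It consumes the identical resize-to-S,
[−1, 1] input pipeline as the discriminator, so the learning strategy is
the only difference between the two.

**Transfer baseline**: a bottleneck residual network (stem 7×7/2 + stages
(3, 4, 6, 3) of 1×1/3×3/1×1 blocks, global average pooling) with a new
binary sigmoid head; all backbone layers except the top
`n_trainable_layers = 5` weight-bearing ones are frozen (frozen batch-norm
layers use running statistics and receive no updates). "Top 5 layers" is
interpreted as the last five weight-bearing layers, configurable. No
natural-image pretrained weights are bundled; a weights file in the
package's own state layout can be supplied, and otherwise the backbone
starts from random initialisation, which exercises the full
freezing/fine-tuning mechanics but not the benefit of pretraining — results
for this baseline are therefore mechanical, not scientific, claims.

## Optimisation

ESGAN uses Adam (β₁ = 0.9, β₂ = 0.999) at the stated 1e-4 for both
submodels. For the supervised baselines the learning rate is not pinned by
the method description; this implementation defaults to 1e-3 (the Keras
default, the framework the original pipeline ran on) because at 1e-4 the
sigmoid head ranks test chips correctly long before its probabilities
straddle the 0.5 decision threshold, which conflates calibration speed with
classifier quality at desk-scale step budgets.

Batches are balanced: batch_size/2 labeled + batch_size/2 unlabeled chips
per step, the labeled half drawn with replacement when the labeled pool is
smaller than the half-batch (the 1%-budget case) and without replacement
otherwise. The unlabeled half is drawn only from the masked pool; whether
labeled chips should also enter the unsupervised phases is unspecified, and
keeping the pools disjoint makes the ablation (`use_unlabeled=False`)
clean.

Early stopping monitors validation overall accuracy of the supervised head:
only a strict improvement resets the patience clock, but among equally good
epochs the most recent weights are kept (otherwise a run that reaches its
best OA early is restored to a needlessly under-trained snapshot). Training
histories record the four losses and validation OA per epoch.

## Data model, splits and budgets

Chips are square H×W×3 arrays with a declared value range ([0, 1] for
storage, [−1, 1] after the affine map x → 2x − 1 that matches the
generator's Tanh). Resizing is bilinear with half-pixel centres. Splits
follow 80:20 train/test then 80:20 train/validation, sizes by round-half-up
(3,921 chips → 3,137 training pool), seed-deterministic, with the test set
held fixed across annotation budgets. A budget reveals ceil(fraction · n)
labels — the ceiling rule reproduces the full-scale design's pairs 1% → 32
and 10% → 314 of 3,137 (that design's 30% → 941 is instead floor/round; the
ceiling rule is kept and the one-chip discrepancy accepted) — stratified by
class via largest-remainder apportionment with at least one chip per class,
preventing degenerate single-class label sets at 1%. The remainder is
returned with labels masked to a sentinel that every supervised entry point
rejects, so a masked label cannot leak into training.

## Tabular descriptors

Per band (R, G, B): median, range (max − min), population standard
deviation, and 75th/95th/99th percentiles by linear interpolation between
order statistics — 18 features, band-major order. The percentile method and
the ddof = 0 standard deviation are documented choices so the sort-based
test oracle is exact. KNN uses k = 10; the random forest grid-searches
n_estimators ∈ {100, 300, 500} × max_depth ∈ {4, 8, 16, ∞} by 5-fold
cross-validated accuracy (the tuned parameters are named in the method; the
grid itself is this package's choice).

## Metrics

Positive class = panicles visible. OA = (TP+TN)/total;
F1 = TP/(TP + (FP+FN)/2), defined as 0 with a warning when TP = FP = FN = 0;
hard labels threshold probabilities at 0.5 (ties to class 0). ROC curves
threshold at every distinct score; AUC is the trapezoid area and equals the
tie-corrected normalised Mann–Whitney U, which the tests verify. Sweep
summaries report mean and sd (ddof = 1) over 3 repeats, each repeat a fresh
split with the test set fixed across budgets.

## Grad-CAM

For a query chip the gradient of the target-class **log-odds**
(l_target − mean of the other logits) is taken with respect to the
activations following the last convolution (post-nonlinearity,
pre-pooling); channel weights are the spatial means of those gradients; the
weighted channel sum is rectified (standard practice, though the original
step list omits the ReLU), min–max scaled **per image** to 0–255 (a
constant map becomes all zeros) and bilinearly upsampled to the chip size.

## Synthetic chips

The generator renders what the classifier actually keys on in the real
imagery: a brownish textured soil background; a roughly circular green
canopy with radial intensity falloff, multiplicative texture, and per-chip
hue/size/position jitter standing in for genotype diversity; and, for the
positive class only, 3–8 bright silver-white Gaussian speckles (panicles)
placed uniformly in the upper half of the canopy disc, where panicles top
the culms. Gaussian pixel noise is added, values are clipped to [0, 1] and
quantised to the 8-bit grid so PNG round trips are lossless. Per-chip
provenance (speckle mask, canopy geometry) is retained for evaluation and
never shown to classifiers.

Default intensities (soil 0.22, canopy green 0.45 ± 0.06, panicle
brightness 0.88, noise sd 0.035) are free choices — the source imagery's
appearance statistics are not published — set so that the classes are
cleanly separable by texture-aware models while a global green-percentile
threshold degrades as panicle brightness approaches the canopy level (a
property the tests assert). What the generator does **not** emulate:
occlusion and shadows, within-canopy structure, multi-plant plots,
perspective, illumination drift between flights, or the long-tailed
phenotypic diversity of a real breeding population. Passing the benchmark
therefore demonstrates that the training machinery learns the intended
signal at small label budgets, not that the accuracy numbers transfer to
real UAV data. One visible consequence: because the class signal is a set
of globally bright speckles, the per-band percentile descriptors capture it
almost perfectly and the tabular baselines saturate near OA 1.0 at the full
budget on synthetic chips, unlike on real imagery where they trail the
convolutional models.

## Benchmark problem sizes

The label-efficiency benchmark uses 2,500 chips at 48×48 (divisible by 4
for the generator and small enough for pure-NumPy training), split
1,600/400/500, with a 32-label budget (1.6% of the pool, mirroring the
32-of-3,137 headline case) and the 1,568-chip remainder unlabeled. ESGAN
trains up to 8 epochs × 25 balanced steps at batch 32; the CNN up to 60
single-batch epochs at 32 labels or 10 epochs at the full budget — a few
hundred Adam steps per model, the point where validation OA plateaus on
this data. The 3-seed comparison reports means, as in the full-scale
protocol's 3 training/testing iterations.

## Known limitations

- One CPU, NumPy-only: wall-clock scales linearly with pixels × channels;
  the 72-pixel default is practical for inference and short fine-tuning,
  while the bundled benchmark trains at 48.
- The transfer baseline's scientific content (pretraining benefit) is
  inert without a weights file.
- Batch-norm running statistics are collected under dropout noise, so very
  short trainings can show a gap between train-mode and inference-mode
  behaviour; the early-stopping rule (keep the latest equally-good
  snapshot) mitigates this.
- The synthetic generator's simplifications above; in particular the
  positive/negative classes differ *only* by speckles, so there is no
  label noise and no ambiguous intermediate phenology stage.
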