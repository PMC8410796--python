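# Methods

## Problem setting

Binary classification of dermoscopic skin-lesion images into melanoma
(positive, minority) and nevus (negative, majority).  Training sets in this
domain are strongly imbalanced (roughly one melanoma per three to four
nevi at full scale, and much worse in screening populations), and a network
trained with a conventional per-sample loss converges to a high-specificity
/ low-sensitivity operating point: the gradient mass is dominated by the
majority class.  The toolkit's purpose is to train models whose sensitivity
and specificity are jointly high and close to each other, and to quantify
operating points rigorously.

## The balanced class-wise loss

For a mini-batch of M examples with P positives and N negatives, scores
ŷ ∈ (0,1) from a sigmoid output:

- `l_MSE  = (1/M) Σ (y − ŷ)²`
- `l_PMSE = (1/P) Σ_{y=1} (1 − ŷ)²`  (mean squared error on positives)
- `l_NMSE = (1/N) Σ_{y=0} ŷ²`        (mean squared error on negatives)
- `l_CLF  = a (l_PMSE + l_NMSE)² + b (l_PMSE − l_NMSE)²`

Minimising `l_PMSE` / `l_NMSE` maximises SEN / SPE respectively; the sum
term drives the total class-wise error down while the difference term
penalises their imbalance, and squaring prevents sign cancellation.  The
coefficients default to a = 0.5, b = 1.0 (b > a makes the imbalance
penalty dominate); they are plain configuration with no automatic tuning.

Properties maintained by tests: non-negativity; `l_CLF = 0` iff both
class-wise errors are zero (for a > 0); symmetry under class swap; strict
monotonicity in |l_PMSE − l_NMSE| at fixed sum; the analytic gradient
(used for backpropagation) matches central finite differences to 1e−5; and
the closed form on confusion counts (`l_PMSE = FN/(TP+FN)`,
`l_NMSE = FP/(TN+FP)`) agrees with the continuous form on hard 0/1 scores
to 1e−12.

Of the three worked confusion examples on a 20/80 set, the middle one is
commonly quoted with a loss value of 0.050; the definition above gives
0.5·(0.3)² + 1.0·(0.1)² = 0.055, and the implementation follows the
definition.

Degenerate batches: in training mode a batch missing one class contributes
the defined class term plus zero for the missing class (with a warning), so
the loss stays total under unconstrained samplers; in strict (evaluation)
mode a missing class raises an error.  Class-wise losses are computed per
mini-batch, never accumulated across the epoch — the fixed-ratio sampler
exists precisely to make the per-batch composition meaningful.  `l_CLF`
needs no numerical clipping; the BCE/focal baselines clip scores at 1e−7.

## Fixed-ratio mini-batches

`positive_fraction` (default: the training-set prevalence; 0.5 gives fully
balanced batches) fixes `n_pos = round(fraction × batch_size)` positives in
every batch.  An epoch is one full pass over the majority class:
`floor(N_neg / (batch_size − n_pos))` batches of a shuffled negative
partition, with positives drawn from an independently shuffled cycling
stream that reshuffles on exhaustion — within each pass every positive is
used exactly once before any repeats, so all minority samples are equally
represented.  A final short batch that cannot honour the ratio is dropped
(the naive baseline sampler keeps it).  The naive sampler is a uniform
shuffle-and-chunk partition whose per-batch class counts are random; at 5%
prevalence it routinely produces batches with zero positives.

## Preprocessing and real-time augmentation

Photographs are center-cropped to 4:3, resized to 256×192 px and scaled to
[0,1].  Augmentation draws, per selection of an image into a batch, one
random affine warp: rotation in ±5°, horizontal/vertical shifts in ±5% of
the image size, shear intensity in ±0.05, zoom in ±5%, with nearest-edge
fill.  (These range conventions mirror the common augmentation-API meaning
of "0.05" for shift/zoom/shear; all are configurable.)  The four transforms
are composed into a single affine matrix applied in the listed order with
one bilinear resampling pass, avoiding cumulative interpolation blur.
Because the warp is drawn on selection, two epochs see different versions
of the same photograph (on-draw rather than offline augmentation).  Flips
and color-space augmentation are deliberately not included.

## Architecture

The classifier is a pluggable backbone (any map from H×W×3 batches to
fixed-length feature vectors) under a reformed fully-connected head:
dense 1024 → dense 512, each hidden layer as dense → ReLU → batch
normalization → dropout 0.5, then dense 1 → sigmoid.  BN/dropout are
specified per hidden layer without an inherent order; the default places BN
after the activation, and `bn_before_activation` flips it.  The backbone's
feature vector is assumed to be global-average-pooled.

For CPU-scale work the packaged tiny backbone is used everywhere: 4×4
average pooling, four stride-2 3×3 convolutions (8→16→32→64 channels) with
ReLU, then global average pooling — ~25k parameters, 64 features,
deterministic per seed.  A large pretrained CNN (e.g. a DenseNet with
1664-dim pooled features) fills the same contract when weights and data are
available at scale.

The network engine itself (convolution via im2col, dense, batch
normalization, inverted dropout, Adam with bias correction, explicit
backward passes, float64 parameters) is implemented in
`dermbalance.nn`; its gradients are finite-difference-tested layer by
layer.

## Training

Three scenarios isolate the contributions: ORI (naive batches,
conventional loss), BON (fixed-ratio batches, conventional loss), BLF
(fixed-ratio batches, CLF).  MSE is the default conventional loss (BCE and
focal are available).  With a shared seed the three scenarios start from
identical weights and differ only through batch composition and loss.

Optimizer: Adam, lr 1e−4, β₁ 0.9, β₂ 0.999, decay 0.  The learning rate is
driven per iteration by a triangular2 cyclical schedule between
base_lr 1e−7 and max_lr 1e−4 with a half-cycle of 4 epochs (converted to
iterations via the realized iterations-per-epoch), the ceiling halving
after each full cycle:

```
s = step_size_epochs × iterations_per_epoch
cycle = floor(1 + it/(2s));  x = |it/s − 2·cycle + 1|
lr = base_lr + (max_lr − base_lr) · max(0, 1 − x) / 2^(cycle−1)
```

Validation loss is the scenario's own loss on the whole validation set at
once (a single batch), and the checkpoint kept is the epoch with minimum
validation loss.  Training aborts on a non-finite loss.  SEN/SPE monitoring
during training uses threshold 0.5.  Determinism is best effort: all
randomness (weights, sampler, augmentation, dropout) derives from the
scenario seed; history comparisons tolerate 1e−6 for BLAS-level drift.

## Evaluation

Predicted positive iff score ≥ threshold (ties to positive) — one
convention fixed package-wide because sweep tables depend on it.  The ROC
is computed over all distinct score thresholds; AUC by trapezoid, which the
tests hold equal to brute-force Mann–Whitney pair counting (ties half) on
hundreds of random instances.  Threshold sweeps report, per SEN floor, the
largest threshold achieving it (and per SPE floor the smallest), each point
recomputable from raw scores.  Balanced-threshold selection offers
min |SEN − SPE| (ties: larger SEN+SPE, then larger threshold) and Youden's
J; which criterion a published balanced point used is generally unstated,
so both are exposed behind a flag.  Reader comparison interpolates the
curve linearly at each reader's false-positive rate; "outperformed" means
strictly below the curve, with on-curve points (within 1e−9) reported
separately.  A transcription of a published reader study's group operating
points (11 groups of 157 dermatologists) ships as a CSV fixture — input
data for demonstration reports, not computed claims.

## Synthetic data

The generator renders a skin-tone background (Gaussian-smoothed speckle)
plus one elliptical lesion whose darkness, border irregularity (sinusoidal
boundary perturbation), asymmetry (elongation) and relative size are drawn
from class-conditional normal distributions; `separability` ∈ [0,1] scales
the shift of the positive-class means, from identically distributed classes
(chance AUC) to nearly feature-separable ones.  Splits are stratified
80/10/10 per class; everything is deterministic per seed.  Rendering is
deliberately simple: the goal is controllable statistical structure, not
photorealism.  A held-out 20-positive/80-negative benchmark generator with
an independent seed mirrors the composition of a public 100-image
dermoscopic benchmark.  A binormal score generator (negatives N(0,1),
positives N(√2·Φ⁻¹(AUC*), 1), sigmoid-mapped) supplies score sets with a
prescribed expected AUC for evaluation-harness work.

What passing tests show — and what they do not: the synthetic images share
with real dermoscopy only the coarse statistical skeleton (imbalance, a
minority class distinguished by darker/larger/more irregular lesions,
overlapping class distributions, pixel noise).  They lack hair, rulers,
color variegation, acquisition artifacts and the full intra-class
diversity of real lesions, so results here demonstrate that the training
machinery behaves as designed under controlled imbalance, not that any
particular clinical accuracy would be attained on real data.

## The scaled-down scenario experiment

The canonical experiment (also run by `scripts/acceptance.py` and the test
suite) uses 188 positives / 1688 negatives — a 10% prevalence giving a
150/1350 training split — rendered at 64×80 px, the tiny backbone, batch
size 32, 10 epochs, real-time augmentation on, and five seeds; per seed the
three scenarios share data and initial weights.  Rendering resolution,
epochs and backbone size are desk-scale choices so the whole comparison
runs in minutes on one CPU.

Separability is set to 0.35 for this experiment.  The value was chosen so
that the synthetic task sits in the regime the method addresses: with
substantially overlapping classes, an MSE-trained model scores ambiguous
minority examples toward the prior and sensitivity collapses below
specificity (on some seeds to near zero), which is the documented behavior
of conventional losses on imbalanced medical data.  At high separability
the task saturates, every scenario scores well, and the comparison measures
nothing.  The expected (and tested) outcome is ordinal, not numeric: the
median |SEN − SPE| gap at threshold 0.5 is smaller for BLF than for BON,
and BLF's median sensitivity exceeds ORI's.  Headline accuracies from
full-scale training on real dermoscopy data (AUC ≈ 0.94 with SEN 0.85 /
SPE 0.95) require GPU-scale training on external datasets and are outside
what this package's tests claim.

## Known limitations

- The numpy engine is single-process and CPU-bound; it is sized for the
  tiny backbone, not for training large CNNs.
- CLF is binary-only; no multi-class extension or cost-matrix learning.
- No confidence intervals on AUC and no calibration analysis.
- Batch-norm statistics are per-batch only (no synchronization concept),
  and dropout masks are layer-local generators — adequate for the packaged
  architectures, not a general-purpose framework.
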