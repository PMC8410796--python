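# dermbalance

A training and evaluation toolkit for **binary melanoma-vs-nevus
classification on class-imbalanced image data**.  It is aimed at people
building medical-image classifiers who observe the classic imbalance
pathology: a model trained with a conventional loss on a dataset with few
melanomas reaches high specificity (SPE) but poor sensitivity (SEN) — the
clinically costly direction of error.

The toolkit packages four cooperating ideas:

1. **A balanced class-wise loss (CLF).**  With
   `l_PMSE = (1/P) Σ_{y_i=1} (1 − ŷ_i)²` and
   `l_NMSE = (1/N) Σ_{y_i=0} ŷ_i²` — the mean squared errors restricted to
   the positive and negative examples of a mini-batch — the training loss is

   ```
   l_CLF = a · (l_PMSE + l_NMSE)² + b · (l_PMSE − l_NMSE)²      (a = 0.5, b = 1.0)
   ```

   The sum term drives both class-wise errors down (pushing SEN + SPE up);
   the difference term penalizes any imbalance between them (pushing
   |SEN − SPE| toward zero); squaring keeps both terms non-negative and
   differentiable.  On hard 0/1 predictions, `l_PMSE = FN/(TP+FN)` and
   `l_NMSE = FP/(TN+FP)`, so the loss has an exact closed form on a
   confusion matrix, used for verification and reporting.

2. **Fixed-ratio mini-batches.**  Every training batch contains exactly
   `n_pos` minority and `batch_size − n_pos` majority examples, so the
   class-wise terms of CLF are always defined and equally informed at every
   iteration.  Negatives are a shuffled partition (one full pass per
   epoch); positives cycle through independent reshuffles.

3. **A reformed fully-connected head** on top of any convolutional feature
   extractor: dense 1024 → dense 512, each with ReLU, batch normalization
   and dropout 0.5, then a single sigmoid output.  A ~25k-parameter tiny
   convolutional backbone is included so everything trains on a CPU in
   minutes; a large pretrained backbone can be plugged in through the same
   contract (batch of H×W×3 rasters → batch of feature vectors).

4. **Operating-point evaluation**: SEN/SPE from confusion counts, full ROC
   with trapezoidal AUC (equal to the Mann–Whitney pair statistic),
   threshold sweeps against SEN/SPE targets, balanced-threshold selection
   (min |SEN − SPE| or Youden), and comparison of the model's ROC against
   human reader operating points (a transcription of a published
   157-dermatologist reader study ships as input fixture data).

Training follows three named scenarios used for controlled comparison —
**ORI** (naive batches + MSE), **BON** (fixed-ratio batches + MSE), **BLF**
(fixed-ratio batches + CLF) — with Adam (lr 1e-4, β₁ 0.9, β₂ 0.999) under a
*triangular2* cyclical learning rate (base 1e-7, max 1e-4, half-cycle 4
epochs, ceiling halved every cycle) and min-validation-loss checkpointing.

A seeded synthetic lesion-image generator (elliptical lesions with
class-conditional darkness, border irregularity, asymmetry and size on a
skin-tone textured background, at configurable imbalance and separability)
makes the whole pipeline runnable and testable fully offline.

## Worked example

```python
from dermbalance import ConfusionCounts, LossParams, clf_from_confusion, sensitivity, specificity

for name, c in [("Ex1", ConfusionCounts(tp=12, fp=2, tn=78, fn=8)),
                ("Ex2", ConfusionCounts(tp=16, fp=8, tn=72, fn=4)),
                ("Ex3", ConfusionCounts(tp=17, fp=10, tn=70, fn=3))]:
    r = clf_from_confusion(c, LossParams(a=0.5, b=1.0))
    print(name, f"SEN {100*sensitivity(c):.1f} SPE {100*specificity(c):.1f} "
                f"MSE {r.mse:.2f} CLF {r.clf:.7f}")
```

prints

```
Ex1 SEN 60.0 SPE 97.5 MSE 0.10 CLF 0.2309375
Ex2 SEN 80.0 SPE 90.0 MSE 0.12 CLF 0.0550000
Ex3 SEN 85.0 SPE 87.5 MSE 0.13 CLF 0.0384375
```

From Ex1 to Ex3 sensitivity rises from 60% to 85% and SEN/SPE tighten, yet
plain MSE *increases* — it prefers the unbalanced model.  CLF decreases,
ranking the balanced model best; that inversion is the reason to train with
it on imbalanced data.

The `examples/` directory has one short script per capability
(`loss_worked_examples.py`, `fixed_ratio_batches.py`, `train_blf_tiny.py`,
`threshold_analysis.py`, `scenario_comparison.py`); each builds a small
input, runs the method and explains what it prints.  A thin CLI wraps the
same library calls:

```bash
dermbalance generate --seed 1 --out data/           # synthetic dataset + manifest
dermbalance train --scenario BLF --manifest data/manifest.csv --out run/
dermbalance evaluate --checkpoint run/checkpoint_BLF.npz --manifest data/manifest.csv --out eval/
dermbalance compare --seed 0 --n-seeds 3 --out cmp/ # ORI vs BON vs BLF table
```

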