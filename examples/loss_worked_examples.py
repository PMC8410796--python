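"""Worked examples of the class-wise loss family on a 100-image set.

Three confusion matrices on an imbalanced 20-positive / 80-negative set
show why plain MSE is a poor training signal under class imbalance: from
the first to the third example sensitivity improves from 60% to 85% and the
SEN/SPE balance tightens, yet MSE *increases* — while the balanced custom
loss (CLF) decreases, correctly preferring the balanced model.
"""

from dermbalance import ConfusionCounts, LossParams, clf_from_confusion, sensitivity, specificity, accuracy

examples = [
    ("Example 1", ConfusionCounts(tp=12, fp=2, tn=78, fn=8)),
    ("Example 2", ConfusionCounts(tp=16, fp=8, tn=72, fn=4)),
    ("Example 3", ConfusionCounts(tp=17, fp=10, tn=70, fn=3)),
]

params = LossParams(a=0.5, b=1.0)
print(f"{'':10s} {'ACC':>6s} {'SEN':>6s} {'SPE':>6s} {'MSE':>8s} {'CLF':>9s}")
for name, counts in examples:
    loss = clf_from_confusion(counts, params)
    print(
        f"{name:10s} {100*accuracy(counts):6.1f} {100*sensitivity(counts):6.1f} "
        f"{100*specificity(counts):6.1f} {loss.mse:8.2f} {loss.clf:9.7f}"
    )
print("\nCLF falls while MSE rises: only CLF ranks the balanced model best.")
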