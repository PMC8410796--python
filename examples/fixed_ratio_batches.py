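"""Fixed-ratio versus naive mini-batch composition on imbalanced labels.

With 5% positives, naive shuffling routinely yields batches with no
minority example at all — iterations in which a class-wise loss learns
nothing about melanoma.  The fixed-ratio sampler pins the per-batch
composition exactly.
"""

import numpy as np

from dermbalance import SamplingPlan, make_epoch, naive_epoch

labels = np.array([1] * 10 + [0] * 190)
np.random.default_rng(0).shuffle(labels)

plan = SamplingPlan(batch_size=32, positive_fraction=0.25, seed=0)
fixed = [int(labels[b].sum()) for b in make_epoch(labels, plan)]
naive = [int(labels[b].sum()) for b in naive_epoch(labels, 32, rng=0)]

print("positives per batch, fixed-ratio sampler:", fixed)
print("positives per batch, naive sampler:      ", naive)
print(f"\nnaive batches with zero positives: {naive.count(0)} of {len(naive)}")
print("the fixed-ratio sampler guarantees every batch carries minority examples.")
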