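import numpy as np
import pytest

from dermbalance.losses import LabeledBatch


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_batch(rng, size=None, ensure_both_classes=True) -> LabeledBatch:
    """A random valid batch of continuous scores and 0/1 labels."""
    m = int(rng.integers(2, 64)) if size is None else size
    scores = rng.random(m)
    labels = (rng.random(m) < rng.uniform(0.1, 0.9)).astype(int)
    if ensure_both_classes:
        labels[0] = 1
        labels[-1] = 0
    return LabeledBatch(scores=scores, labels=labels)


def brute_force_auc(scores, labels) -> float:
    """Mann-Whitney pairwise concordance with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
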