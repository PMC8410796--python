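"""Unit and property tests for the class-wise loss family."""

import numpy as np
import pytest

from dermbalance.errors import InvalidInputError
from dermbalance.losses import (
    BCELoss,
    CLFLoss,
    ConfusionCounts,
    FocalLoss,
    LabeledBatch,
    LossParams,
    MSELoss,
    binary_cross_entropy,
    clf,
    clf_from_confusion,
    clf_gradient,
    focal_loss,
    mse,
    nmse,
    pmse,
)

from conftest import random_batch

# the three worked confusion-matrix examples on a 20-positive/80-negative set
EXAMPLES = {
    1: ConfusionCounts(tp=12, fp=2, tn=78, fn=8),
    2: ConfusionCounts(tp=16, fp=8, tn=72, fn=4),
    3: ConfusionCounts(tp=17, fp=10, tn=70, fn=3),
}


class TestBatchValidation:
    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(InvalidInputError):
            LabeledBatch(scores=np.array([]), labels=np.array([]))
        with pytest.raises(InvalidInputError):
            LabeledBatch(scores=np.array([0.5]), labels=np.array([1, 0]))

    def test_rejects_out_of_range_scores_and_labels(self):
        with pytest.raises(InvalidInputError):
            LabeledBatch(scores=np.array([1.2]), labels=np.array([1]))
        with pytest.raises(InvalidInputError):
            LabeledBatch(scores=np.array([0.5]), labels=np.array([2]))

    def test_params_must_be_nonnegative_with_positive_sum(self):
        with pytest.raises(InvalidInputError):
            LossParams(a=-0.1, b=1.0)
        with pytest.raises(InvalidInputError):
            LossParams(a=0.0, b=0.0)


class TestPointValues:
    def test_mse_perfect_prediction_is_zero(self):
        b = LabeledBatch(scores=np.array([0.0, 1.0, 1.0]), labels=np.array([0, 1, 1]))
        assert mse(b) == 0.0

    def test_mse_hand_example(self):
        b = LabeledBatch(scores=np.array([0.5, 0.5]), labels=np.array([0, 1]))
        assert mse(b) == pytest.approx(0.25)

    def test_pmse_hand_example(self):
        b = LabeledBatch(scores=np.array([0.5, 1.0]), labels=np.array([1, 1]))
        assert pmse(b) == pytest.approx(0.125)

    def test_nmse_hand_example(self):
        b = LabeledBatch(scores=np.array([0.2, 0.4]), labels=np.array([0, 0]))
        assert nmse(b) == pytest.approx(0.10)

    def test_pmse_requires_positives_in_strict_mode(self):
        b = LabeledBatch(scores=np.array([0.2, 0.4]), labels=np.array([0, 0]))
        with pytest.raises(InvalidInputError):
            pmse(b, strict=True)
        with pytest.warns(RuntimeWarning):
            assert pmse(b, strict=False) == 0.0

    def test_clf_derived_counts_example(self):
        # pmse=4/20=0.2, nmse=8/80=0.1 -> 0.5*0.09 + 1.0*0.01 = 0.055
        r = clf_from_confusion(EXAMPLES[2])
        assert r.pmse == pytest.approx(0.2)
        assert r.nmse == pytest.approx(0.1)
        assert r.clf == pytest.approx(0.055)

    def test_confusion_requires_both_classes(self):
        with pytest.raises(InvalidInputError):
            clf_from_confusion(ConfusionCounts(tp=0, fp=3, tn=7, fn=0))

    def test_bce_half_score(self):
        b = LabeledBatch(scores=np.array([0.5]), labels=np.array([1]))
        assert binary_cross_entropy(b) == pytest.approx(np.log(2), rel=1e-9)

    def test_focal_gamma_zero_is_alpha_weighted_bce(self, rng):
        for _ in range(20):
            b = random_batch(rng)
            expected = np.mean(
                np.where(b.labels == 1, 0.25, 0.75)
                * -np.log(np.clip(np.where(b.labels == 1, b.scores, 1 - b.scores), 1e-7, None))
            )
            assert focal_loss(b, gamma=0.0, alpha=0.25) == pytest.approx(expected, rel=1e-9)


class TestProperties:
    def test_all_losses_nonnegative(self, rng):
        params = LossParams()
        for _ in range(300):
            b = random_batch(rng)
            assert mse(b) >= 0
            assert pmse(b) >= 0
            assert nmse(b) >= 0
            assert clf(b, params) >= 0
            assert binary_cross_entropy(b) >= 0
            assert focal_loss(b) >= 0

    def test_clf_zero_iff_both_class_losses_zero(self, rng):
        params = LossParams(a=0.5, b=1.0)
        perfect = LabeledBatch(scores=np.array([1.0, 1.0, 0.0]), labels=np.array([1, 1, 0]))
        assert clf(perfect, params) == 0.0
        for _ in range(200):
            b = random_batch(rng)
            if pmse(b) > 1e-9 or nmse(b) > 1e-9:
                assert clf(b, params) > 0.0

    def test_hard_score_equivalence(self, rng):
        params = LossParams()
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 40, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            counts = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            closed = clf_from_confusion(counts, params)
            hard = counts.to_batch()
            assert abs(closed.clf - clf(hard, params)) < 1e-12
            assert abs(closed.mse - mse(hard)) < 1e-12
            assert abs(closed.pmse - pmse(hard)) < 1e-12
            assert abs(closed.nmse - nmse(hard)) < 1e-12

    def test_balance_penalty_increases_with_gap_at_fixed_sum(self):
        # hold pmse + nmse fixed, widen |pmse - nmse|: clf strictly increases
        params = LossParams(a=0.5, b=1.0)
        total = 0.6
        values = []
        for gap in np.linspace(0.0, total, 13):
            p = (total + gap) / 2
            n = (total - gap) / 2
            values.append(params.a * total**2 + params.b * gap**2)
            assert values[-1] == pytest.approx(
                params.a * (p + n) ** 2 + params.b * (p - n) ** 2
            )
        assert all(v2 > v1 for v1, v2 in zip(values, values[1:]))

    def test_clf_symmetric_under_class_swap(self, rng):
        params = LossParams()
        for _ in range(100):
            b = random_batch(rng)
            swapped = LabeledBatch(scores=1.0 - b.scores, labels=1 - b.labels)
            # swapping labels and reflecting scores swaps (pmse, nmse)
            assert clf(b, params) == pytest.approx(clf(swapped, params), abs=1e-12)

    def test_clf_gradient_matches_finite_differences(self, rng):
        params = LossParams()
        for _ in range(25):
            b = random_batch(rng)
            scores = np.clip(b.scores, 0.01, 0.99)
            b = LabeledBatch(scores=scores, labels=b.labels)
            analytic = clf_gradient(b, params)
            eps = 1e-6
            for i in range(0, b.scores.size, max(1, b.scores.size // 5)):
                up = scores.copy()
                up[i] += eps
                dn = scores.copy()
                dn[i] -= eps
                numeric = (
                    clf(LabeledBatch(up, b.labels), params)
                    - clf(LabeledBatch(dn, b.labels), params)
                ) / (2 * eps)
                assert analytic[i] == pytest.approx(numeric, abs=1e-5)

    def test_worked_examples_show_clf_mse_disagreement(self):
        # across the three confusion examples the balanced loss decreases
        # while plain MSE increases: the motivation for the custom loss
        results = [clf_from_confusion(EXAMPLES[k]) for k in (1, 2, 3)]
        clfs = [r.clf for r in results]
        mses = [r.mse for r in results]
        assert clfs == sorted(clfs, reverse=True)
        assert mses == sorted(mses)


class TestTrainableLosses:
    @pytest.mark.parametrize(
        "loss", [MSELoss(), BCELoss(), FocalLoss(), CLFLoss(LossParams())]
    )
    def test_gradients_match_finite_differences(self, loss, rng):
        scores = rng.uniform(0.05, 0.95, 16)
        labels = (rng.random(16) < 0.4).astype(int)
        labels[0], labels[-1] = 1, 0
        g = loss.grad(scores, labels)
        eps = 1e-6
        for i in range(16):
            up, dn = scores.copy(), scores.copy()
            up[i] += eps
            dn[i] -= eps
            num = (loss.value(up, labels) - loss.value(dn, labels)) / (2 * eps)
            assert g[i] == pytest.approx(num, abs=1e-5)
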