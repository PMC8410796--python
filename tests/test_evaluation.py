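"""Tests for ROC/AUC, threshold sweeps, balanced points and reader comparison."""

import numpy as np
import pytest

from dermbalance.errors import InvalidInputError, UndefinedMetricError
from dermbalance.evaluation import (
    OperatingPoint,
    ReaderPoint,
    ROCCurve,
    accuracy,
    balanced_threshold,
    confusion_at_threshold,
    readers_outperformed,
    roc_and_auc,
    sensitivity,
    specificity,
    threshold_sweep,
)
from dermbalance.losses import ConfusionCounts
from dermbalance.synth import generate_scores

from conftest import brute_force_auc


class TestSenSpe:
    # the three worked confusion examples and their printed SEN/SPE/ACC
    @pytest.mark.parametrize(
        "counts, sen, spe, acc",
        [
            (ConfusionCounts(12, 2, 78, 8), 0.60, 0.975, 0.90),
            (ConfusionCounts(16, 8, 72, 4), 0.80, 0.90, 0.88),
            (ConfusionCounts(17, 10, 70, 3), 0.85, 0.875, 0.87),
        ],
    )
    def test_worked_examples(self, counts, sen, spe, acc):
        assert sensitivity(counts) == pytest.approx(sen)
        assert specificity(counts) == pytest.approx(spe)
        assert accuracy(counts) == pytest.approx(acc)

    def test_perfect_recall(self):
        assert sensitivity(ConfusionCounts(tp=5, fp=0, tn=3, fn=0)) == 1.0

    def test_empty_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(tp=0, fp=1, tn=1, fn=0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(tp=1, fp=0, tn=0, fn=1))

    def test_ties_predicted_positive(self):
        counts = confusion_at_threshold([0.5, 0.5], [1, 0], 0.5)
        assert counts.tp == 1 and counts.fp == 1


class TestROC:
    def test_perfect_separation(self):
        curve = roc_and_auc([0.9, 0.8, 0.4, 0.3, 0.2], [1, 1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_one_discordant_pair(self):
        # swap one positive/negative pair: AUC = 5/6
        curve = roc_and_auc([0.9, 0.8, 0.3, 0.4, 0.2], [1, 1, 1, 0, 0])
        assert curve.auc == pytest.approx(5 / 6)

    def test_chance_level_for_independent_scores(self):
        scores, labels = generate_scores(4000, 4000, auc_target=0.5, seed=3)
        assert roc_and_auc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_curve_monotonicity_and_endpoints(self, rng):
        scores, labels = generate_scores(30, 70, auc_target=0.8, seed=1)
        curve = roc_and_auc(scores, labels)
        assert np.all(np.diff(curve.thresholds) <= 0)
        assert np.all(np.diff(curve.sen) >= -1e-12)
        assert np.all(np.diff(curve.spe) <= 1e-12)
        assert (curve.sen[0], curve.spe[0]) == (0.0, 1.0)
        assert (curve.sen[-1], curve.spe[-1]) == (1.0, 0.0)

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        # includes tied scores via coarse rounding
        for trial in range(60):
            m = int(rng.integers(4, 50))
            labels = (rng.random(m) < 0.4).astype(int)
            labels[0], labels[1] = 1, 0
            scores = np.round(rng.random(m), 1)
            assert roc_and_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-10
            )

    def test_monotone_transform_invariance(self, rng):
        scores, labels = generate_scores(25, 60, auc_target=0.85, seed=9)
        base = roc_and_auc(scores, labels).auc
        assert roc_and_auc(scores**3, labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_and_auc(np.exp(2 * scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_and_auc([0.1, 0.9], [1, 1])


def _enumerate_best_sen_point(scores, labels, target):
    """Brute-force oracle: largest threshold among all candidate thresholds
    achieving SEN >= target."""
    best = None
    for t in np.concatenate([[max(scores) + 1], np.unique(scores)]):
        c = confusion_at_threshold(scores, labels, t)
        if sensitivity(c) >= target and (best is None or t > best[0]):
            best = (t, sensitivity(c), specificity(c))
    return best


class TestThresholdSweep:
    def test_full_sensitivity_target(self, rng):
        scores, labels = generate_scores(10, 40, auc_target=0.9, seed=4)
        rows = threshold_sweep(scores, labels, sen_targets=(1.0,))
        point = rows[0]["point"]
        assert point.sen == 1.0
        assert point.threshold <= scores[labels == 1].min()
        assert point.spe == np.mean(scores[labels == 0] < point.threshold)

    def test_perfectly_separated_scores(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        for target in (0.5, 1.0):
            rows = threshold_sweep(scores, labels, sen_targets=(target,))
            assert rows[0]["point"].spe == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(30):
            scores = np.round(rng.random(10), 1)
            labels = (rng.random(10) < 0.5).astype(int)
            labels[0], labels[1] = 1, 0
            for target in (0.3, 0.6, 0.9, 1.0):
                row = threshold_sweep(scores, labels, sen_targets=(target,))[0]
                t, sen, spe = _enumerate_best_sen_point(scores, labels, target)
                assert row["point"].threshold == pytest.approx(t)
                assert row["point"].sen == pytest.approx(sen)
                assert row["point"].spe == pytest.approx(spe)

    def test_points_recomputable_from_raw_scores(self, rng):
        scores, labels = generate_scores(20, 80, auc_target=0.944, seed=8)
        targets = (1.0, 0.95, 0.9, 0.85, 0.8)
        for row in threshold_sweep(scores, labels, sen_targets=targets, spe_targets=targets):
            p = row["point"]
            c = confusion_at_threshold(scores, labels, p.threshold)
            assert sensitivity(c) == pytest.approx(p.sen)
            assert specificity(c) == pytest.approx(p.spe)


class TestBalancedThreshold:
    def test_perfect_separation_gives_sen_spe_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        for criterion in ("min_gap", "youden"):
            point = balanced_threshold(scores, labels, criterion)
            assert point.sen == 1.0 and point.spe == 1.0

    def test_symmetric_distributions_balance(self):
        scores, labels = generate_scores(300, 300, auc_target=0.9, seed=2)
        point = balanced_threshold(scores, labels, "min_gap")
        assert abs(point.sen - point.spe) < 0.05

    def test_min_gap_matches_enumeration_with_ties(self, rng):
        for trial in range(30):
            scores = np.round(rng.random(12), 1)
            labels = (rng.random(12) < 0.4).astype(int)
            labels[0], labels[1] = 1, 0
            point = balanced_threshold(scores, labels, "min_gap")
            candidates = []
            for t in np.concatenate([[scores.max() + 1], np.unique(scores)]):
                c = confusion_at_threshold(scores, labels, t)
                candidates.append(
                    (abs(sensitivity(c) - specificity(c)),
                     -(sensitivity(c) + specificity(c)), -t)
                )
            assert (
                abs(point.sen - point.spe), -(point.sen + point.spe), -point.threshold
            ) == pytest.approx(min(candidates))

    def test_unknown_criterion_rejected(self):
        with pytest.raises(InvalidInputError):
            balanced_threshold([0.1, 0.9], [0, 1], "accuracy")


class TestReadersOutperformed:
    def _toy_curve(self):
        # staircase through (0,0) -> (0,0.5) -> (0.2,0.5) -> (0.2,0.9) -> (1,1)
        sen = np.array([0.0, 0.5, 0.5, 0.9, 1.0])
        fpr = np.array([0.0, 0.0, 0.2, 0.2, 1.0])
        return ROCCurve(thresholds=np.linspace(1, 0, 5), sen=sen, spe=1 - fpr, auc=0.9)

    def test_manual_geometry(self):
        curve = self._toy_curve()
        readers = [
            ReaderPoint(sen=0.3, spe=0.95),   # below: curve sen at fpr .05 = .5
            ReaderPoint(sen=0.5, spe=1.0),    # on the vertex (0, 0.5)
            ReaderPoint(sen=0.9, spe=0.6),    # curve at fpr .4 -> .925: below
            ReaderPoint(sen=0.99, spe=0.6),   # above the interpolated segment
            ReaderPoint(sen=0.9, spe=0.8),    # on the vertex (0.2, 0.9)
        ]
        n_out, flags = readers_outperformed(curve, readers)
        assert n_out == 2
        assert flags == ["below", "on-curve", "below", "above", "on-curve"]

    def test_perfect_classifier_outperforms_all_imperfect_readers(self):
        curve = roc_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        readers = [ReaderPoint(sen=0.8, spe=0.9), ReaderPoint(sen=0.99, spe=0.2)]
        n_out, flags = readers_outperformed(curve, readers)
        assert n_out == 2

    def test_reader_point_validation(self):
        with pytest.raises(InvalidInputError):
            ReaderPoint(sen=1.2, spe=0.5)
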