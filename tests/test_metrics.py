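"""Ranking metrics and threshold selection vs brute-force and sklearn."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from dtimap.metrics import (
    confusion_at_threshold,
    evaluate_scores,
    pr_auc,
    roc_auc,
    select_threshold,
)
from oracles import oracle_f1, oracle_roc_auc


class TestRocAuc:
    def test_hand_case(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.05

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_all_pairs_oracle_and_sklearn(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 100))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            ours = roc_auc(scores, labels)
            assert ours == pytest.approx(oracle_roc_auc(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=4, max_size=50),
        st.integers(0, 10**6),
    )
    def test_invariant_under_monotone_transform(self, scores, seed):
        # round so that distinct scores stay distinct under exp in float64
        scores = np.round(np.asarray(scores), 3)
        labels = np.random.default_rng(seed).integers(0, 2, len(scores))
        if labels.min() == labels.max():
            return
        base = roc_auc(scores, labels)
        assert roc_auc(3 * scores + 2, labels) == pytest.approx(base, abs=1e-12)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)


class TestPrAuc:
    def test_hand_case(self):
        assert pr_auc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_prevalence(self):
        assert pr_auc([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_no_positive_raises(self):
        with pytest.raises(ValueError):
            pr_auc([0.2, 0.3], [0, 0])

    def test_matches_sklearn_average_precision(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 100))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            assert pr_auc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestSelectThreshold:
    def test_separable_returns_midpoint_in_gap(self):
        t = select_threshold([0.2, 0.6, 0.7], [0, 1, 1])
        assert 0.2 < t < 0.6
        assert oracle_f1([0.2, 0.6, 0.7], [0, 1, 1], t) == 1.0

    def test_all_positive_labels_predicts_everything(self):
        t = select_threshold([0.3, 0.5, 0.9], [1, 1, 1])
        assert t < 0.3

    def test_exhaustively_optimal_on_random_inputs(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            t = select_threshold(scores, labels)
            f1_at_t = oracle_f1(scores, labels, t)
            # every candidate threshold, including extremes
            for cand in np.concatenate([[-1.0, 2.0], np.unique(scores), np.unique(scores) - 1e-9]):
                assert f1_at_t >= oracle_f1(scores, labels, cand) - 1e-12

    def test_tie_breaks_to_lowest_threshold(self):
        # both candidate regions give F1 = 1 is impossible; craft equal-F1 case
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [1, 1, 1, 1]
        assert select_threshold(scores, labels) < 0.1


class TestEvaluateScores:
    def test_perfect_scores(self):
        rep = evaluate_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], threshold=0.5)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.roc_auc == 1.0 and rep.pr_auc == 1.0
        assert (rep.n_pos, rep.n_neg) == (2, 2)

    def test_threshold_zero_all_positive(self):
        rep = evaluate_scores([0.9, 0.1, 0.5, 0.4], [1, 0, 1, 0], threshold=0.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_printed_confusion_arithmetic(self):
        # TP=3, FN=1, TN=2, FP=2 at threshold 0.5
        scores = [0.9, 0.8, 0.7, 0.2, 0.6, 0.7, 0.1, 0.3]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        tp, fp, tn, fn = confusion_at_threshold(scores, labels, 0.5)
        assert (tp, fp, tn, fn) == (3, 2, 2, 1)
        rep = evaluate_scores(scores, labels, 0.5)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.5)
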