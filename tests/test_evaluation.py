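from itertools import product

import numpy as np
import pytest

from conftest import SMALL_ENCODER, SMALL_FOREST
from hetdti.evaluation import (
    all_negative_pairs,
    make_splits,
    pr_auc,
    roc_auc,
    run_cross_validation,
    score_report,
    threshold_metrics,
)
from oracles import pr_auc_threshold_enum, roc_auc_paircount


def _plan_inputs(n_drugs=10, n_prot=12, n_pos=30, seed=0):
    rng = np.random.default_rng(seed)
    drugs = [f"d{i}" for i in range(n_drugs)]
    prots = [f"p{i}" for i in range(n_prot)]
    all_pairs = [(d, p) for d in drugs for p in prots]
    idx = rng.choice(len(all_pairs), size=n_pos, replace=False)
    pos = [all_pairs[i] for i in idx]
    neg = [pr for pr in all_pairs if pr not in set(pos)]
    return pos, neg


class TestSplits:
    def test_sizes_follow_protocol(self):
        pos, neg = _plan_inputs(n_drugs=20, n_prot=20, n_pos=100)
        plan = make_splits(pos, neg, seed=1)
        test_pos = [p for p, y in plan.test_pairs if y == 1]
        test_neg = [p for p, y in plan.test_pairs if y == 0]
        assert len(test_pos) == 20 and len(test_neg) == 20
        for train, val in plan.folds:
            val_pos = [p for p, y in val if y == 1]
            val_neg = [p for p, y in val if y == 0]
            assert len(val_pos) == 16 and len(val_neg) == 16
            train_pos = [p for p, y in train if y == 1]
            train_neg = [p for p, y in train if y == 0]
            assert len(train_pos) == 64 and len(train_neg) == 64

    def test_fold_validation_positives_partition_cv_positives(self):
        pos, neg = _plan_inputs()
        plan = make_splits(pos, neg, seed=3)
        test_pos = {p for p, y in plan.test_pairs if y == 1}
        cv_pos = set(pos) - test_pos
        val_sets = [{p for p, y in val if y == 1} for _, val in plan.folds]
        assert set().union(*val_sets) == cv_pos
        for a, b in product(range(5), range(5)):
            if a < b:
                assert not (val_sets[a] & val_sets[b])

    def test_test_and_cv_pools_disjoint(self):
        pos, neg = _plan_inputs()
        plan = make_splits(pos, neg, seed=2)
        test = {p for p, _ in plan.test_pairs}
        for train, val in plan.folds:
            fold_pairs = {p for p, _ in train} | {p for p, _ in val}
            assert not (test & fold_pairs)

    def test_same_seed_identical_plan(self):
        pos, neg = _plan_inputs()
        assert make_splits(pos, neg, seed=9) == make_splits(pos, neg, seed=9)

    def test_too_few_positives_errors(self):
        with pytest.raises(ValueError):
            make_splits([("d0", "p0")], [("d1", "p1")] * 10, seed=0)

    def test_no_fold_trains_on_its_heldout_positives(self):
        pos, neg = _plan_inputs()
        plan = make_splits(pos, neg, seed=4)
        for train, val in plan.folds:
            train_pos = {p for p, y in train if y == 1}
            val_pos = {p for p, y in val if y == 1}
            assert not (train_pos & val_pos)


class TestMetricOracles:
    def test_roc_matches_pair_counting_exhaustively(self):
        # all score/label combinations on <= 8 samples (coarse score grid)
        rng = np.random.default_rng(0)
        for n in (2, 4, 6, 8):
            for _ in range(30):
                scores = rng.integers(0, 4, size=n) / 3.0
                labels = rng.integers(0, 2, size=n)
                if labels.min() == labels.max():
                    continue
                assert roc_auc(scores, labels) == pytest.approx(
                    roc_auc_paircount(scores, labels))

    def test_roc_hand_case(self):
        assert roc_auc([0.9, 0.8, 0.4], [1, 0, 1]) == pytest.approx(0.5)

    def test_roc_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_pr_matches_threshold_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(3, 10))
            scores = rng.random(n).round(2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            assert pr_auc(scores, labels) == pytest.approx(
                pr_auc_threshold_enum(scores, labels))

    def test_pr_perfect_ranking_is_one(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_pr_all_positive_is_one(self):
        assert pr_auc([0.3, 0.9], [1, 1]) == pytest.approx(1.0)

    def test_threshold_metrics_confusion_arithmetic(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.2, 0.1, 0.05]
        labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        f1, acc, rec = threshold_metrics(scores, labels, threshold=0.5)
        assert rec == pytest.approx(0.75)
        assert acc == pytest.approx(0.8)
        assert f1 == pytest.approx(0.75)

    def test_all_negative_predictions_degenerate_f1(self):
        f1, acc, rec = threshold_metrics([0.1, 0.2, 0.3], [1, 0, 1], threshold=0.5)
        assert f1 == 0.0 and rec == 0.0

    def test_permuted_labels_null_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.random(60)
        labels = np.array([1] * 20 + [0] * 40)
        aucs = []
        for _ in range(50):
            perm = rng.permutation(labels)
            aucs.append(roc_auc(scores, perm))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestCrossValidation:
    def test_five_reports_and_ranges(self, small_dataset, small_similarities):
        s_d, s_p = small_similarities
        pos = sorted(small_dataset.interactions.edges)
        neg = all_negative_pairs([d.drug_id for d in small_dataset.drugs],
                                 [p.protein_id for p in small_dataset.proteins],
                                 set(pos))
        plan = make_splits(pos, neg, seed=3)
        reports, mean = run_cross_validation(s_d, s_p, plan, SMALL_ENCODER, SMALL_FOREST)
        assert len(reports) == 5
        for r in reports + [mean]:
            for v in (r.roc_auc, r.pr_auc, r.f1, r.accuracy, r.recall):
                assert 0.0 <= v <= 1.0

    def test_signal_beats_permuted_null(self, small_dataset, small_similarities):
        s_d, s_p = small_similarities
        pos = sorted(small_dataset.interactions.edges)
        neg = all_negative_pairs([d.drug_id for d in small_dataset.drugs],
                                 [p.protein_id for p in small_dataset.proteins],
                                 set(pos))
        plan = make_splits(pos, neg, seed=5)
        from hetdti.evaluation import run_fold
        train, val = plan.folds[0]
        scores, labels = run_fold(s_d, s_p, train, val, SMALL_ENCODER, SMALL_FOREST)
        real = roc_auc(scores, labels)
        rng = np.random.default_rng(0)
        null = np.mean([roc_auc(scores, rng.permutation(labels)) for _ in range(10)])
        assert real > null
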