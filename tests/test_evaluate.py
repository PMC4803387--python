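import math

import numpy as np
import pytest

from plbind.evaluate import (
    ConfusionCounts,
    StratificationError,
    UndefinedMetricError,
    confusion_from_scores,
    confusion_metrics,
    cross_validate,
    holdout_split,
    roc_auc,
    write_report_json,
    write_report_tsv,
    write_roc_tsv,
)
from plbind.learners import HyperParams
from conftest import pair_count_auc


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_four_example_hand_case(self):
        # concordant pairs: (0.9>0.8), (0.9>0.1), (0.7<0.8), (0.7>0.1) -> 3/4
        _, auc = roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        _, auc = roc_auc(scores, labels)
        assert 0.45 <= auc <= 0.55

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            # quantized scores force ties
            scores = np.round(rng.normal(size=n), 1)
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        curve, _ = roc_auc(scores, labels)
        np.testing.assert_allclose(curve[0], [0, 0])
        np.testing.assert_allclose(curve[-1], [1, 1])
        assert (np.diff(curve[:, 0]) >= 0).all()
        assert (np.diff(curve[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_label_swap_maps_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        _, auc = roc_auc(scores, labels)
        _, swapped = roc_auc(-scores, 1 - labels)
        assert swapped == pytest.approx(auc, abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        perm = rng.permutation(60)
        c1, a1 = roc_auc(scores, labels)
        c2, a2 = roc_auc(scores[perm], labels[perm])
        assert a1 == pytest.approx(a2, abs=1e-12)
        np.testing.assert_allclose(c1, c2)


class TestConfusionMetrics:
    def test_perfect(self):
        assert confusion_metrics(ConfusionCounts(10, 0, 10, 0)) == (100.0, 100.0, 1.0)

    def test_chance(self):
        sens, spec, mcc = confusion_metrics(ConfusionCounts(5, 5, 5, 5))
        assert (sens, spec, mcc) == (50.0, 50.0, 0.0)

    def test_direct_formula(self):
        tp, fp, tn, fn = 3, 1, 7, 2
        sens, spec, mcc = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert sens == pytest.approx(100 * tp / (tp + fn))
        assert spec == pytest.approx(100 * tn / (tn + fp))
        expected = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc == pytest.approx(expected)

    def test_zero_denominator_gives_zero_mcc(self):
        sens, spec, mcc = confusion_metrics(ConfusionCounts(0, 0, 5, 5))
        assert mcc == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(UndefinedMetricError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_bounds_and_swap_negation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 30, size=4))
            _, _, mcc = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert -1.0 <= mcc <= 1.0
            _, _, swapped = confusion_metrics(ConfusionCounts(fn, tn, fp, tp))
            assert swapped == pytest.approx(-mcc)

    def test_confusion_from_scores(self):
        counts = confusion_from_scores([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], 0.5)
        assert (counts.TP, counts.FN, counts.FP, counts.TN) == (1, 1, 1, 1)
        assert counts.total == 4


class TestCrossValidate:
    def test_separable_pooled_auc(self, separable_data):
        data, _ = separable_data
        rep = cross_validate(data, HyperParams("svm", w=3, sigma=8.0), folds=5, seed=0)
        assert rep.pooled["auc"] >= 0.99
        assert len(rep.folds) == 5
        assert rep.threshold == 0.0

    def test_deterministic(self, separable_data):
        data, _ = separable_data
        r1 = cross_validate(data, HyperParams("rf", w=3, n_trees=50), folds=5, seed=3)
        r2 = cross_validate(data, HyperParams("rf", w=3, n_trees=50), folds=5, seed=3)
        assert r1.pooled == r2.pooled
        assert r1.folds == r2.folds
        np.testing.assert_array_equal(r1.roc, r2.roc)

    def test_minimal_two_fold_four_examples(self):
        from plbind.profiles import LabeledDataset

        X = np.zeros((4, 21))
        X[:, 0] = [0.0, 0.1, 5.0, 5.1]
        y = np.array([0, 0, 1, 1])
        data = LabeledDataset(X=X, y=y, meta=[("s", i) for i in range(4)], w=1)
        rep = cross_validate(data, HyperParams("svm", w=1, sigma=3.0), folds=2, seed=0)
        for v in rep.pooled.values():
            assert np.isfinite(v)

    def test_leave_one_out_on_separable(self, separable_data):
        data, _ = separable_data
        rep = cross_validate(data, HyperParams("svm", w=3, sigma=8.0), folds=len(data.y), seed=0)
        assert rep.pooled["auc"] >= 0.99

    def test_stratification_error(self):
        from plbind.profiles import LabeledDataset

        X = np.zeros((6, 21))
        y = np.array([1, 0, 0, 0, 0, 0])
        data = LabeledDataset(X=X, y=y, meta=[("s", i) for i in range(6)], w=1)
        with pytest.raises(StratificationError):
            cross_validate(data, HyperParams("svm", w=1), folds=3, seed=0)

    def test_nn_rf_threshold_is_half(self, separable_data):
        data, _ = separable_data
        rep = cross_validate(data, HyperParams("rf", w=3, n_trees=50), folds=3, seed=0)
        assert rep.threshold == 0.5


class TestHoldoutSplit:
    def test_sizes_100_at_15pct(self):
        from plbind import fixtures as fx

        data, _ = fx.gen_labeled_features(31, n_pos=50, n_neg=50, w=3, separation_sigma=1.0)
        train, test = holdout_split(data, 0.15, seed=0)
        assert len(test.y) == 15 and len(train.y) == 85

    def test_stratified_rounding(self):
        from plbind import fixtures as fx

        data, _ = fx.gen_labeled_features(32, n_pos=40, n_neg=60, w=3, separation_sigma=1.0)
        train, test = holdout_split(data, 0.15, seed=0)
        assert int(test.y.sum()) == 6
        assert len(test.y) - int(test.y.sum()) == 9

    def test_reproducible_and_disjoint(self):
        from plbind import fixtures as fx

        data, _ = fx.gen_labeled_features(33, n_pos=30, n_neg=30, w=3)
        t1 = holdout_split(data, 0.15, seed=5)
        t2 = holdout_split(data, 0.15, seed=5)
        assert t1[1].meta == t2[1].meta
        assert set(t1[0].meta).isdisjoint(t1[1].meta)

    def test_bad_fraction(self):
        from plbind import fixtures as fx

        data, _ = fx.gen_labeled_features(34, n_pos=10, n_neg=10, w=3)
        with pytest.raises(ValueError):
            holdout_split(data, 0.0, seed=0)


def test_report_writers(tmp_path, separable_data):
    data, _ = separable_data
    rep = cross_validate(data, HyperParams("svm", w=3, sigma=8.0), folds=3, seed=0)
    write_report_json(rep, tmp_path / "r.json")
    write_report_tsv(rep, tmp_path / "r.tsv")
    write_roc_tsv(rep, tmp_path / "roc.tsv")
    import json

    payload = json.loads((tmp_path / "r.json").read_text())
    assert payload["pooled"]["auc"] == pytest.approx(rep.pooled["auc"], abs=1e-6)
    lines = (tmp_path / "r.tsv").read_text().splitlines()
    assert lines[0].startswith("fold\t") and lines[-1].startswith("pooled")
    assert (tmp_path / "roc.tsv").read_text().startswith("fpr\ttpr")
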