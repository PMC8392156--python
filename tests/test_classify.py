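"""Classifiers, confusion-matrix metrics and repeated-run aggregation."""

import numpy as np
import pytest

import oilspec as o
from oilspec.classify import METHODS, ConfusionMatrix, compute_metrics


def make_separable(n_per_class=50, p=20, seed=0):
    """Five Gaussian classes with widely separated means (disjoint supports
    at this spread), linearly separable for every method."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(5):
        centre = np.zeros(p)
        centre[c] = 20.0
        X.append(centre + 0.5 * rng.standard_normal((n_per_class, p)))
        y += [f"class{c}"] * n_per_class
    return np.vstack(X), np.array(y)


def tally_metrics_oracle(counts, class_names):
    """Brute-force per-class one-vs-rest tally from first principles."""
    out = {}
    total = counts.sum()
    for i, name in enumerate(class_names):
        tp = counts[i, i]
        fn = sum(counts[i, j] for j in range(len(class_names)) if j != i)
        fp = sum(counts[j, i] for j in range(len(class_names)) if j != i)
        tn = total - tp - fn - fp
        out[name] = dict(
            sens=100 * tp / (tp + fn) if tp + fn else np.nan,
            spec=100 * tn / (tn + fp) if tn + fp else np.nan,
            prec=100 * tp / (tp + fp) if tp + fp else np.nan,
            acc=100 * (tp + tn) / total,
        )
    return out


class TestTrainAndEval:
    @pytest.mark.parametrize("method", METHODS)
    def test_separable_classes_perfectly_recovered(self, method):
        X, y = make_separable()
        cm, metrics = o.train_and_eval(X, y, method, split_seed=1,
                                       cv_training_accuracy=False)
        assert metrics.tpr == 100.0

    def test_deterministic_confusion_matrix(self, labelled_fused):
        a, _ = o.train_and_eval(labelled_fused.X, labelled_fused.class_labels, "KNN",
                                split_seed=2, cv_training_accuracy=False)
        b, _ = o.train_and_eval(labelled_fused.X, labelled_fused.class_labels, "KNN",
                                split_seed=2, cv_training_accuracy=False)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_row_sums_equal_holdout_support(self):
        X, y = make_separable(n_per_class=50)
        cm, _ = o.train_and_eval(X, y, "DT", split_seed=0, cv_training_accuracy=False)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), np.full(5, 10))

    def test_training_accuracy_reported_from_cv(self):
        X, y = make_separable(n_per_class=30, p=5)
        _, metrics = o.train_and_eval(X, y, "KNN", split_seed=0)
        assert metrics.accuracy_training == 100.0

    def test_unknown_method_rejected(self):
        X, y = make_separable(n_per_class=10, p=6)
        with pytest.raises(ValueError):
            o.train_and_eval(X, y, "RF", split_seed=0)

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array(["a"] * 6 + ["b"] * 2)
        with pytest.raises(ValueError):
            o.train_and_eval(X, y, "KNN", split_seed=0)


class TestComputeMetrics:
    def test_binary_collapse_hand_example(self):
        # TP=9, FN=1, FP=2, TN=8 for the first class
        cm = ConfusionMatrix(np.array([[9, 1], [2, 8]]), ("pos", "neg"))
        m = compute_metrics(cm)
        assert m.sensitivity["pos"] == pytest.approx(90.0)
        assert m.specificity["pos"] == pytest.approx(80.0)
        assert m.class_accuracy["pos"] == pytest.approx(85.0)
        assert m.precision["pos"] == pytest.approx(100 * 9 / 11)

    def test_identity_matrix_all_100(self):
        cm = ConfusionMatrix(np.eye(5, dtype=int) * 9, tuple("abcde"))
        m = compute_metrics(cm)
        assert m.tpr == 100.0
        for c in "abcde":
            assert m.sensitivity[c] == m.specificity[c] == m.precision[c] == 100.0

    def test_single_predicted_column(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[:, 0] = 20  # every sample predicted as the first class
        m = compute_metrics(ConfusionMatrix(counts, tuple("abcde")))
        assert m.precision["a"] == pytest.approx(20.0)
        for c in "bcde":
            assert np.isnan(m.precision[c])  # undefined, never imputed
        assert m.tpr == pytest.approx(20.0)

    def test_agrees_with_tally_oracle_on_random_matrices(self, rng):
        names = tuple("abcde")
        for _ in range(50):
            counts = rng.integers(0, 30, size=(5, 5))
            if counts.sum() == 0:
                continue
            m = compute_metrics(ConfusionMatrix(counts, names))
            oracle = tally_metrics_oracle(counts, names)
            for c in names:
                for got, want in (
                    (m.sensitivity[c], oracle[c]["sens"]),
                    (m.specificity[c], oracle[c]["spec"]),
                    (m.precision[c], oracle[c]["prec"]),
                    (m.class_accuracy[c], oracle[c]["acc"]),
                ):
                    if np.isnan(want):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(want)


class TestRepeatRuns:
    def test_identical_runs_have_zero_sd(self):
        X, y = make_separable(n_per_class=30, p=5)
        rs = o.repeat_runs(X, y, "KNN", n_runs=5, cv_training_accuracy=False)
        agg = rs.aggregate()
        assert agg["TPR"]["sd"] == 0.0
        assert agg["TPR"]["median"] == agg["TPR"]["mean"] == 100.0

    def test_retains_one_result_per_run(self, labelled_fused):
        rs = o.repeat_runs(labelled_fused.X, labelled_fused.class_labels, "DT",
                           n_runs=3, seeds=(1, 2, 3), cv_training_accuracy=False)
        assert len(rs.per_run) == 3
        assert len(rs.confusion_matrices) == 3

    def test_median_matches_sort_oracle(self, labelled_fused):
        rs = o.repeat_runs(labelled_fused.X, labelled_fused.class_labels, "DT",
                           n_runs=5, cv_training_accuracy=False)
        vals = sorted(m.tpr for m in rs.per_run)
        assert rs.aggregate()["TPR"]["median"] == pytest.approx(vals[len(vals) // 2])

    def test_fewer_than_two_runs_rejected(self):
        X, y = make_separable(n_per_class=10, p=6)
        with pytest.raises(ValueError):
            o.repeat_runs(X, y, "KNN", seeds=(1,))
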