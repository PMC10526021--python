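import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from selffi.metrics import (ConfusionCounts, RocCurve, accuracy, auc,
                            auc_trapezoid, confusion, f1, precision, recall,
                            report, roc_curve)


def rank_auc(scores, labels):
    """Mann–Whitney oracle: concordant positive–negative fraction, ties ½."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    r = rankdata(scores)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    return (r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        curve = roc_curve(np.array([0.9, 0.1]), np.array([1, 0]))
        pts = list(zip(curve.fpr, curve.tpr))
        assert (0.0, 1.0) in pts
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([0.2, 0.4]), np.array([1, 1]))

    def test_monotone_coordinates_on_random_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        curve = roc_curve(scores, labels)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_invalid_curve_rejected(self):
        with pytest.raises(ValueError):
            RocCurve(fpr=np.array([0.0, 0.5, 0.2]), tpr=np.array([0, 0.5, 1.0]))


class TestAuc:
    def test_ideal_and_random_classifiers(self):
        perfect = roc_curve(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0]))
        assert auc_trapezoid(perfect) == pytest.approx(1.0)
        diagonal = RocCurve(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]))
        assert auc_trapezoid(diagonal) == pytest.approx(0.5)

    def test_matches_rank_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                rank_auc(scores, labels), abs=1e-9)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        base = auc(scores, labels)
        assert auc(np.exp(3 * scores), labels) == pytest.approx(base, abs=1e-12)
        assert auc(np.log(scores + 1e-9), labels) == pytest.approx(base, abs=1e-12)

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12)


class TestConfusionMetrics:
    def test_basic_tally(self):
        c = confusion(np.array([0.9, 0.2]), np.array([1, 0]), 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_all_zero_scores(self):
        c = confusion(np.zeros(5), np.array([1, 1, 0, 0, 0]), 0.5)
        assert c.tp == 0 and c.fp == 0 and c.fn == 2 and c.tn == 3

    def test_counts_conserve_n(self, rng):
        scores = rng.random(37)
        labels = rng.integers(0, 2, 37)
        assert confusion(scores, labels).n == 37

    @pytest.mark.parametrize("counts, expected", [
        (ConfusionCounts(50, 30, 10, 10), {"accuracy": 0.8}),
        (ConfusionCounts(3, 0, 1, 2),
         {"precision": 0.75, "recall": 0.6, "f1": 2 * 0.45 / 1.35}),
    ])
    def test_hand_computed_values(self, counts, expected):
        fns = {"accuracy": accuracy, "precision": precision,
               "recall": recall, "f1": f1}
        for name, want in expected.items():
            assert fns[name](counts) == pytest.approx(want, abs=1e-12)

    def test_f1_is_harmonic_mean_fixed_point(self):
        # precision == recall == 0.6  ->  F1 == 0.6
        c = ConfusionCounts(tp=6, tn=0, fp=4, fn=4)
        assert precision(c) == recall(c) == pytest.approx(0.6)
        assert f1(c) == pytest.approx(0.6)

    def test_zero_denominator_warns_not_crashes(self):
        c = ConfusionCounts(tp=0, tn=5, fp=0, fn=0)
        with pytest.warns(UserWarning, match="precision"):
            assert precision(c) == 0.0
        with pytest.warns(UserWarning, match="recall"):
            assert recall(c) == 0.0


def toy_table(scores, labels, classes=("dm", "em")):
    rows = []
    for k, cls in enumerate(classes):
        for i, (s, l) in enumerate(zip(scores[k], labels[k])):
            rows.append({"image_id": f"img{i}", "class": cls,
                         "probability": s, "label": l})
    return pd.DataFrame(rows)


class TestReport:
    def test_perfect_scores_give_unit_metrics(self):
        table = toy_table([[0.9, 0.8, 0.1], [0.7, 0.2, 0.1]],
                          [[1, 1, 0], [1, 0, 0]])
        rep = report(table, threshold=0.5)
        assert all(rep.per_class["auc"] == 1.0)
        assert rep.macro["accuracy"] == 1.0

    def test_scores_equal_labels_accuracy_one(self):
        table = toy_table([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]],
                          [[1, 0, 1], [0, 1, 0]])
        rep = report(table, threshold=0.5)
        assert rep.macro["accuracy"] == 1.0

    def test_macro_equals_mean_of_per_class(self):
        rng = np.random.default_rng(4)
        table = toy_table(rng.random((2, 30)), rng.integers(0, 2, (2, 30)))
        rep = report(table)
        for name in ("auc", "accuracy", "f1", "precision", "recall"):
            assert rep.macro[name] == pytest.approx(
                rep.per_class[name].mean(), abs=1e-12)

    def test_shuffled_label_null_gives_chance_auc(self):
        rng = np.random.default_rng(6)
        n, k = 200, 6
        scores = rng.random((k, n))
        labels = rng.integers(0, 2, (k, n))
        table = toy_table(scores, labels, classes=[f"c{i}" for i in range(k)])
        rep = report(table)
        assert rep.macro["auc"] == pytest.approx(0.5, abs=0.1)

    def test_single_label_class_excluded_from_macro_auc(self):
        table = toy_table([[0.9, 0.1, 0.6], [0.5, 0.4, 0.6]],
                          [[1, 0, 1], [1, 1, 1]])
        with pytest.warns(UserWarning, match="excluded"):
            rep = report(table)
        assert rep.skipped_auc_classes == ("em",)
        assert rep.macro["auc"] == pytest.approx(rep.per_class.loc["dm", "auc"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            report(pd.DataFrame())
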