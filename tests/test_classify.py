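"""Train/test split, cross-validated decision tree, evaluation report."""

import numpy as np
import pandas as pd
import pytest

from mstates.classify import (
    crossvalidate_tree,
    evaluate_classifier,
    feature_columns,
    round_half_up,
    split_train_test,
    summarize_report,
)
from mstates.errors import InvalidArgumentError


def _toy_features(n_ad=56, n_hc=38, separable=False, seed=0):
    rng = np.random.default_rng(seed)
    n = n_ad + n_hc
    groups = ["AD"] * n_ad + ["HC"] * n_hc
    df = pd.DataFrame({
        "subject": [f"S{i:03d}" for i in range(n)],
        "group": groups,
        "f1": rng.normal(size=n),
        "f2": rng.normal(size=n),
    })
    if separable:
        df["f1"] = np.where(df["group"] == "AD", 1.0, -1.0) + 0.01 * df["f1"]
    return df


class _StubModel:
    """Minimal classifier interface for evaluating fixed predictions."""

    def __init__(self, classes, preds, scores):
        self.classes_ = np.asarray(classes)
        self._preds = np.asarray(preds)
        self._scores = np.asarray(scores, dtype=float)

    def predict(self, X):
        return self._preds

    def predict_proba(self, X):
        # column order follows classes_
        pos = self._scores
        return np.column_stack([1 - pos, pos]) if self.classes_[1] == "AD" \
            else np.column_stack([pos, 1 - pos])


class TestSplitTrainTest:
    def test_eight_to_two_ratio_of_full_cohort(self):
        df = _toy_features()
        train, test = split_train_test(df, seed=0)
        assert len(test) == 19  # round(94 * 0.2)
        assert len(train) == 75

    def test_stratification_keeps_both_classes(self):
        df = _toy_features(n_ad=30, n_hc=10)
        for seed in range(5):
            train, test = split_train_test(df, seed=seed)
            assert set(train.group) == {"AD", "HC"}
            assert set(test.group) == {"AD", "HC"}

    def test_same_seed_reproducible(self):
        df = _toy_features()
        a = split_train_test(df, seed=3)
        b = split_train_test(df, seed=3)
        assert a[0].subject.tolist() == b[0].subject.tolist()
        assert a[1].subject.tolist() == b[1].subject.tolist()

    @pytest.mark.parametrize("frac", [0.0, 1.0])
    def test_degenerate_fraction_rejected(self, frac):
        with pytest.raises(InvalidArgumentError):
            split_train_test(_toy_features(), test_fraction=frac)


class TestCrossvalidateTree:
    def test_separable_features_score_perfectly(self):
        df = _toy_features(separable=True)
        scores, tree = crossvalidate_tree(df, ["f1", "f2"], folds=5, seed=0)
        assert np.allclose(scores, 1.0)

    def test_same_seed_identical_folds(self):
        df = _toy_features()
        a, _ = crossvalidate_tree(df, ["f1", "f2"], seed=1)
        b, _ = crossvalidate_tree(df, ["f1", "f2"], seed=1)
        assert np.array_equal(a, b)

    def test_permuted_labels_score_near_chance(self):
        df = _toy_features(n_ad=60, n_hc=60)
        rng = np.random.default_rng(5)
        df["group"] = rng.permutation(df["group"].to_numpy())
        scores, _ = crossvalidate_tree(df, ["f1", "f2"], seed=5)
        assert abs(scores.mean() - 0.5) < 0.15

    def test_single_class_rejected(self):
        df = _toy_features(n_ad=20, n_hc=0)
        with pytest.raises(InvalidArgumentError):
            crossvalidate_tree(df, ["f1", "f2"])


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        df = _toy_features(n_ad=10, n_hc=10)
        y = df["group"].to_numpy()
        model = _StubModel(["AD", "HC"], y, (y == "AD").astype(float))
        rep = evaluate_classifier(model, df, ["f1", "f2"])
        assert rep.accuracy == 1.0
        assert np.allclose(rep.f1, 1.0)
        assert rep.auc == 1.0

    def test_published_confusion_matrix_reproduced(self):
        # the unique integer confusion matrix consistent with the published
        # per-class report at supports 12 (HC) / 17 (AD): [[13, 4], [4, 8]]
        # in (AD, HC) order
        y = ["AD"] * 17 + ["HC"] * 12
        pred = ["AD"] * 13 + ["HC"] * 4 + ["AD"] * 4 + ["HC"] * 8
        df = pd.DataFrame({"group": y, "f1": 0.0, "f2": 0.0})
        scores = np.linspace(0.1, 0.9, 29)
        model = _StubModel(["AD", "HC"], pred, scores)
        rep = evaluate_classifier(model, df, ["f1", "f2"])
        assert rep.accuracy == pytest.approx(21 / 29)
        idx_hc = rep.classes.index("HC")
        idx_ad = rep.classes.index("AD")
        assert rep.precision[idx_hc] == pytest.approx(8 / 12)
        assert rep.recall[idx_ad] == pytest.approx(13 / 17)
        assert rep.support[idx_hc] == 12 and rep.support[idx_ad] == 17

    def test_constant_scores_give_half_auc(self):
        df = _toy_features(n_ad=10, n_hc=10)
        y = df["group"].to_numpy()
        model = _StubModel(["AD", "HC"], np.full(20, "AD"), np.full(20, 0.5))
        rep = evaluate_classifier(model, df, ["f1", "f2"])
        assert rep.auc == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_score_transform(self):
        df = _toy_features(n_ad=15, n_hc=15, seed=2)
        y = df["group"].to_numpy()
        rng = np.random.default_rng(2)
        scores = np.clip(rng.uniform(0.05, 0.95, 30) + 0.3 * (y == "AD"), 0, 1)
        preds = np.where(scores > 0.5, "AD", "HC")
        a = evaluate_classifier(_StubModel(["AD", "HC"], preds, scores),
                                df, ["f1", "f2"])
        b = evaluate_classifier(_StubModel(["AD", "HC"], preds, scores**3),
                                df, ["f1", "f2"])
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_single_class_test_set_warns_but_reports(self):
        df = _toy_features(n_ad=10, n_hc=0)
        model = _StubModel(["AD", "HC"], np.full(10, "AD"), np.ones(10))
        with pytest.warns(UserWarning):
            rep = evaluate_classifier(model, df, ["f1", "f2"])
        assert rep.accuracy == 1.0
        assert np.isnan(rep.auc)


class TestSummarizeReport:
    def test_published_macro_and_weighted_averages(self):
        per_class = {"precision": [0.67, 0.76], "recall": [0.67, 0.76],
                     "f1": [0.67, 0.76]}
        macro, weighted = summarize_report(per_class, [12, 17])
        assert round_half_up(macro["f1"]) == 0.72
        assert round_half_up(weighted["f1"]) == 0.72
        assert round_half_up(weighted["recall"]) == 0.72  # = accuracy

    def test_single_class_macro_equals_weighted(self):
        macro, weighted = summarize_report({"f1": [0.8]}, [7])
        assert macro == weighted

    def test_equal_supports_macro_equals_weighted(self):
        macro, weighted = summarize_report({"f1": [0.5, 0.9]}, [10, 10])
        assert macro["f1"] == pytest.approx(weighted["f1"])

    def test_accuracy_is_support_weighted_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cm = rng.integers(0, 20, size=(2, 2))
            if cm.sum(axis=1).min() == 0:
                continue
            recall = np.diag(cm) / cm.sum(axis=1)
            support = cm.sum(axis=1)
            _, weighted = summarize_report({"recall": recall}, support)
            assert weighted["recall"] == pytest.approx(np.trace(cm) / cm.sum())

    def test_feature_columns_cover_full_metric_vector(self):
        cols = feature_columns()
        assert len(cols) == 28
        assert len(set(cols)) == 28
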