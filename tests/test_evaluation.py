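"""Forest, OOB permutation importance, metrics and nested LOSO."""

import numpy as np
import pandas as pd
import pytest

from runfatigue.errors import ValidationError
from runfatigue.evaluation import (OOBPermutationRandomForest, TrainingSpec,
                                   classification_metrics,
                                   nested_loso_evaluate, select_features)
from runfatigue.sensors import make_configuration
from runfatigue.types import LABELS


def _noise_Xy(n=300, p=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = rng.integers(0, 3, n)
    return X, y


class TestForestImportance:
    def test_same_seed_identical_importances(self):
        X, y = _noise_Xy()
        imps = []
        for _ in range(2):
            f = OOBPermutationRandomForest(n_estimators=30, random_state=5)
            f.fit(X, y)
            imps.append(f.oob_permutation_importance())
        np.testing.assert_array_equal(imps[0], imps[1])

    def test_pure_noise_importances_center_at_zero(self):
        X, y = _noise_Xy(n=500, seed=2)
        f = OOBPermutationRandomForest(n_estimators=50, random_state=3)
        f.fit(X, y)
        imp = f.oob_permutation_importance()
        assert np.abs(imp.mean()) < 0.01
        assert np.all(np.abs(imp) < 0.05)

    def test_perfectly_informative_feature_ranks_first(self):
        X, y = _noise_Xy(n=400, seed=4)
        X[:, 3] = y  # feature 3 equals the class label
        f = OOBPermutationRandomForest(n_estimators=50, random_state=7)
        f.fit(X, y)
        imp = f.oob_permutation_importance()
        assert imp.argmax() == 3
        assert imp[3] > 2 * np.max(np.delete(imp, 3))

    def test_agrees_with_holdout_permutation_importance(self):
        """Independent cross-check: scikit-learn's hold-out permutation
        importance on a plain random forest ranks the same feature first."""
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.inspection import permutation_importance
        X, y = _noise_Xy(n=600, seed=8)
        X[:, 5] = y + 0.3 * np.random.default_rng(9).standard_normal(600)
        rf = RandomForestClassifier(n_estimators=50, random_state=0)
        rf.fit(X[:400], y[:400])
        ref = permutation_importance(rf, X[400:], y[400:], random_state=0)
        ours = OOBPermutationRandomForest(n_estimators=50, random_state=0)
        ours.fit(X, y)
        assert ours.oob_permutation_importance().argmax() == \
            ref.importances_mean.argmax() == 5

    def test_single_class_rejected(self):
        X, _ = _noise_Xy()
        with pytest.raises(ValidationError, match="2 classes"):
            OOBPermutationRandomForest(n_estimators=5).fit(X, np.zeros(len(X)))


class TestSelectFeatures:
    def test_top_12_of_34(self):
        imp = pd.Series(np.linspace(1, 0, 34),
                        index=[f"f{i:02d}" for i in range(34)])
        out = select_features(imp, k=12)
        assert out == [f"f{i:02d}" for i in range(12)]

    def test_ties_break_by_catalogue_order(self):
        imp = pd.Series([0.5, 0.5], index=["L6_accel_std", "L6_accel_peak"])
        out = select_features(imp, k=1)
        assert out == ["L6_accel_peak"]  # earlier catalogue position

    def test_small_mask_returns_all(self):
        imp = pd.Series(np.zeros(5), index=[f"f{i}" for i in range(5)])
        assert len(select_features(imp, k=12)) == 5


class TestMetrics:
    def test_diagonal_is_perfect(self):
        m = classification_metrics(np.diag([5, 7, 9]))
        assert m["accuracy"] == 1.0
        for cls in LABELS:
            assert all(v == 1.0 for v in m["per_class"][cls].values())

    def test_uniform_matrix_is_chance(self):
        m = classification_metrics(np.full((3, 3), 4))
        assert m["accuracy"] == pytest.approx(1 / 3)
        for cls in LABELS:
            assert m["per_class"][cls]["sensitivity"] == pytest.approx(1 / 3)

    def test_hand_computed_example(self):
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 2, 8]])
        m = classification_metrics(cm)
        assert m["accuracy"] == pytest.approx(22 / 30)
        assert m["per_class"][LABELS[0]]["precision"] == pytest.approx(8 / 10)
        assert m["per_class"][LABELS[0]]["sensitivity"] == pytest.approx(8 / 10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(np.zeros((3, 3), dtype=int))


# ---------------------------------------------------------------------------
# nested LOSO on directly constructed tables
# ---------------------------------------------------------------------------

def _synthetic_table(n_subjects=4, rows_per_class=40, informative=True,
                     seed=0):
    """Labeled table over the left thigh+tibia feature mask."""
    cfg = make_configuration(["L4", "L6"])
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for ci, label in enumerate(LABELS):
            X = rng.standard_normal((rows_per_class, len(cfg.feature_mask)))
            if informative:
                X[:, :5] += 3.0 * ci   # strongly class-separated features
            df = pd.DataFrame(X, columns=list(cfg.feature_mask))
            df.insert(0, "subject_id", f"S{s}")
            df.insert(1, "label", label)
            rows.append(df)
    return pd.concat(rows, ignore_index=True), cfg


class TestNestedLOSO:
    def test_test_subject_never_in_training(self):
        table, cfg = _synthetic_table(n_subjects=4, rows_per_class=15)
        audit = []
        nested_loso_evaluate(table, cfg,
                             TrainingSpec(n_trees=10, seed=1), audit=audit)
        assert len(audit) == 4
        for fold in audit:
            assert fold.test_subject not in fold.train_subjects
            for inner in fold.inner_folds:
                assert fold.test_subject not in inner
                assert len(inner) == len(fold.train_subjects) - 1

    def test_selects_twelve_and_finds_signal(self):
        table, cfg = _synthetic_table(n_subjects=4, rows_per_class=30, seed=3)
        report = nested_loso_evaluate(table, cfg,
                                      TrainingSpec(n_trees=20, seed=2))
        for fold in report.folds:
            assert len(fold.selected_features) == 12
            # the five informative features dominate the selection
            assert len(set(fold.selected_features)
                       & set(cfg.feature_mask[:5])) == 5
        assert report.accuracy_mean > 0.9

    def test_aggregate_confusion_totals_and_accuracy_identity(self):
        table, cfg = _synthetic_table(n_subjects=3, rows_per_class=20, seed=5)
        report = nested_loso_evaluate(table, cfg,
                                      TrainingSpec(n_trees=10, seed=4))
        assert report.aggregate_confusion.sum() == len(table)
        # accuracy from the aggregate matrix = row-weighted fold accuracy
        agg_acc = np.trace(report.aggregate_confusion) / len(table)
        weighted = sum(f.accuracy * f.confusion.sum()
                       for f in report.folds) / len(table)
        assert agg_acc == pytest.approx(weighted, abs=1e-12)

    def test_deterministic_given_seed(self):
        table, cfg = _synthetic_table(n_subjects=3, rows_per_class=15, seed=6)
        r1 = nested_loso_evaluate(table, cfg, TrainingSpec(n_trees=10, seed=9))
        r2 = nested_loso_evaluate(table, cfg, TrainingSpec(n_trees=10, seed=9))
        np.testing.assert_array_equal(r1.aggregate_confusion,
                                      r2.aggregate_confusion)
        assert [f.selected_features for f in r1.folds] == \
            [f.selected_features for f in r2.folds]

    def test_too_few_subjects_rejected(self):
        table, cfg = _synthetic_table(n_subjects=2, rows_per_class=10)
        with pytest.raises(ValidationError, match="3 subjects"):
            nested_loso_evaluate(table, cfg, TrainingSpec(n_trees=5))
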