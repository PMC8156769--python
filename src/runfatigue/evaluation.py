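"""Nested leave-one-subject-out (LOSO) fatigue classification.

The classifier is a bagged forest of 100 decision trees with
``sqrt(n_features)`` candidate features per split.  The bootstrap is
drawn with an explicit NumPy generator so that out-of-bag (OOB)
membership is known exactly, which makes OOB permutation importance —
the mean, over trees, of the OOB accuracy drop after permuting one
feature's OOB values — fully reproducible.

Evaluation is nested: the outer loop leaves one test subject out; the
inner loop, over the remaining subjects, repeatedly excludes one further
validation subject, learns OOB permutation importances on the rest,
and averages them.  The 12 best features are selected for every
configuration with more than 12 available features (single-IMU masks
already contain exactly 12), a forest is retrained on the full training
set restricted to the selection, and the held-out subject is scored.
Stride-level rows within a subject are strongly autocorrelated after lap
smoothing, so splits are only ever made at subject level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y, check_array

from .errors import ValidationError
from .features import CATALOGUE_INDEX
from .types import LABELS, EvalReport, FoldResult, SensorConfiguration


@dataclass
class TrainingSpec:
    """Hyperparameters of the nested-LOSO evaluation."""

    n_trees: int = 100
    k_selected: int = 12
    seed: int = 0
    max_features: str | int | float = "sqrt"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees: must be >= 1")
        if self.k_selected < 1:
            raise ValidationError("k_selected: must be >= 1")


class OOBPermutationRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest with explicit bootstrap and OOB permutation importance.

    Parameters
    ----------
    n_estimators : number of trees.
    max_features : candidate features per split (scikit-learn semantics).
    random_state : seed for bootstrap draws, tree randomness and
        importance permutations.

    Attributes (after ``fit``)
    --------------------------
    classes_ : sorted class labels.
    estimators_ : the fitted decision trees.
    bootstrap_indices_ : per-tree bootstrap row indices.
    """

    def __init__(self, n_estimators: int = 100,
                 max_features: str | int | float = "sqrt",
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.shape[0] < 2:
            raise ValidationError("fit: need at least 2 classes")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_estimators)
        self.estimators_ = []
        self.bootstrap_indices_ = []
        for i in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(max_features=self.max_features,
                                          random_state=int(tree_seeds[i]))
            tree.fit(X[idx], y_enc[idx])
            self.estimators_.append(tree)
            self.bootstrap_indices_.append(idx)
        self.n_features_in_ = X.shape[1]
        self._fit_X = X
        self._fit_y = y_enc
        return self

    def _vote(self, per_tree_pred: np.ndarray) -> np.ndarray:
        """Majority vote over trees; ties go to the lowest class index."""
        n_classes = self.classes_.shape[0]
        counts = np.zeros((per_tree_pred.shape[1], n_classes), dtype=int)
        for t in range(per_tree_pred.shape[0]):
            np.add.at(counts, (np.arange(per_tree_pred.shape[1]),
                               per_tree_pred[t]), 1)
        return counts.argmax(axis=1)

    def predict(self, X):
        X = check_array(X, dtype=float)
        preds = np.stack([t.predict(X) for t in self.estimators_]).astype(int)
        return self.classes_[self._vote(preds)]

    def oob_permutation_importance(self) -> np.ndarray:
        """Per-feature mean OOB accuracy drop after permutation.

        Features a tree never splits on contribute a zero drop for that
        tree.  Deterministic given ``random_state``.
        """
        n = self._fit_X.shape[0]
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1)
        drops = np.zeros((len(self.estimators_), self.n_features_in_))
        n_used = 0
        for t, (tree, idx) in enumerate(zip(self.estimators_,
                                            self.bootstrap_indices_)):
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            if oob.size == 0:
                continue
            n_used += 1
            X_oob = self._fit_X[oob]
            y_oob = self._fit_y[oob]
            base = (tree.predict(X_oob).astype(int) == y_oob).mean()
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            for f in used:
                perm = rng.permutation(oob.size)
                X_perm = X_oob.copy()
                X_perm[:, f] = X_oob[perm, f]
                acc = (tree.predict(X_perm).astype(int) == y_oob).mean()
                drops[t, f] = base - acc
        if n_used == 0:
            raise ValidationError("oob importance: no tree has OOB samples")
        return drops.sum(axis=0) / n_used


def select_features(mean_importances: pd.Series, k: int = 12) -> list[str]:
    """Top-``k`` features by mean importance, best first.

    Ties break toward the earlier catalogue position; if ``k`` or fewer
    features are available, all are returned ranked.
    """
    if len(mean_importances) == 0:
        raise ValidationError("select_features: no features given")
    order = sorted(mean_importances.index,
                   key=lambda name: (-mean_importances[name],
                                     CATALOGUE_INDEX.get(name, len(CATALOGUE_INDEX))))
    return order[: min(k, len(order))]


def classification_metrics(confusion: np.ndarray,
                           classes: tuple[str, ...] = LABELS
                           ) -> dict[str, object]:
    """One-vs-rest metrics from a confusion matrix (rows true, cols pred)."""
    cm = np.asarray(confusion)
    if cm.shape != (len(classes), len(classes)):
        raise ValidationError("confusion: wrong shape")
    if np.any(cm < 0):
        raise ValidationError("confusion: counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValidationError("confusion: all-zero matrix")
    out: dict[str, object] = {"accuracy": float(np.trace(cm) / total)}
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * prec * sens / (prec + sens)) if prec + sens else 0.0
        per_class[cls] = {"sensitivity": float(sens), "specificity": float(spec),
                          "precision": float(prec), "f1": float(f1)}
    out["per_class"] = per_class
    return out


@dataclass
class _Fold:
    """Provenance record of one outer fold (kept for auditability)."""

    test_subject: str
    train_subjects: list[str]
    inner_folds: list[tuple[str, ...]] = field(default_factory=list)


def nested_loso_evaluate(table: pd.DataFrame,
                         configuration: SensorConfiguration,
                         spec: TrainingSpec | None = None,
                         audit: list[_Fold] | None = None) -> EvalReport:
    """Nested leave-one-subject-out evaluation of one sensor configuration.

    ``table`` must contain the z-scored smoothed features plus
    ``subject_id`` and ``label`` columns.  ``audit``, if given, is filled
    with the subject partition of every fold.
    """
    spec = spec if spec is not None else TrainingSpec()
    features = [f for f in configuration.feature_mask if f in table.columns]
    if not features:
        raise ValidationError("configuration: empty feature mask for this table")
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 3:
        raise ValidationError("nested LOSO: need at least 3 subjects")
    present = set(table["label"].unique())
    if not set(LABELS) <= present:
        raise ValidationError("nested LOSO: all 3 fatigue classes must be present")

    y_all = table["label"].to_numpy()
    subj_all = table["subject_id"].to_numpy()
    X_all = table[features].to_numpy(dtype=float)
    label_index = {c: i for i, c in enumerate(LABELS)}

    ss = np.random.SeedSequence(spec.seed)
    fold_seeds = ss.spawn(len(subjects))

    folds: list[FoldResult] = []
    aggregate = np.zeros((3, 3), dtype=int)
    for si, test_subject in enumerate(subjects):
        test_mask = subj_all == test_subject
        train_subjects = [s for s in subjects if s != test_subject]
        fold_audit = _Fold(test_subject, train_subjects)
        fold_rng = np.random.default_rng(fold_seeds[si])
        forest_seeds = fold_rng.integers(0, 2**31 - 1,
                                         size=len(train_subjects) + 1)

        if len(features) > spec.k_selected:
            importances = np.zeros(len(features))
            for vi, val_subject in enumerate(train_subjects):
                inner = tuple(s for s in train_subjects if s != val_subject)
                fold_audit.inner_folds.append(inner)
                inner_mask = np.isin(subj_all, inner)
                forest = OOBPermutationRandomForest(
                    n_estimators=spec.n_trees,
                    max_features=spec.max_features,
                    random_state=int(forest_seeds[vi]))
                forest.fit(X_all[inner_mask], y_all[inner_mask])
                importances += forest.oob_permutation_importance()
            importances /= len(train_subjects)
            selected = select_features(pd.Series(importances, index=features),
                                       spec.k_selected)
        else:
            selected = select_features(
                pd.Series(np.zeros(len(features)), index=features),
                len(features))

        cols = [features.index(f) for f in selected]
        train_mask = ~test_mask
        forest = OOBPermutationRandomForest(
            n_estimators=spec.n_trees, max_features=spec.max_features,
            random_state=int(forest_seeds[-1]))
        forest.fit(X_all[train_mask][:, cols], y_all[train_mask])
        pred = forest.predict(X_all[test_mask][:, cols])

        cm = np.zeros((3, 3), dtype=int)
        for yt, yp in zip(y_all[test_mask], pred):
            cm[label_index[yt], label_index[yp]] += 1
        aggregate += cm
        folds.append(FoldResult(
            left_out_subject=test_subject,
            confusion=cm,
            selected_features=selected,
            accuracy=classification_metrics(cm)["accuracy"],
        ))
        if audit is not None:
            audit.append(fold_audit)

    # mean +- STD over folds (sample STD)
    def agg(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    per_fold_metrics = [classification_metrics(f.confusion) for f in folds]
    per_class: dict[str, dict[str, tuple[float, float]]] = {}
    for cls in LABELS:
        per_class[cls] = {
            m: agg([pm["per_class"][cls][m] for pm in per_fold_metrics])
            for m in ("sensitivity", "specificity", "precision", "f1")}
    acc_mean, acc_std = agg([f.accuracy for f in folds])

    report = EvalReport(
        configuration=configuration,
        classes=LABELS,
        folds=folds,
        aggregate_confusion=aggregate,
        per_class_metrics=per_class,
        accuracy_mean=acc_mean,
        accuracy_std=acc_std,
    )
    report.validate()
    return report
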