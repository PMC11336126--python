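"""Decision-tree disease classification from microstate features.

Protocol: stratified 8:2 train/test split, five-fold cross-validation on
the training set (no hyperparameter tuning — a CART tree with Gini impurity
and library defaults), refit on the full training set, and evaluation on
the held-out test set with per-class precision/recall/F1/support, macro and
support-weighted averages, a confusion matrix, and a ROC curve built from
the tree's leaf class fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidArgumentError

#: The per-subject microstate feature columns used for classification (k=4):
#: 4 durations + 4 occurrences + 4 coverages + 12 transition probabilities
#: + mean duration + mean occurrence + GEV + total time = 28 features.
def feature_columns(class_labels: tuple[str, ...] = ("A", "B", "C", "D")) -> list[str]:
    cols = [f"duration_{c}" for c in class_labels]
    cols += [f"occurrence_{c}" for c in class_labels]
    cols += [f"coverage_{c}" for c in class_labels]
    cols += [f"tp_{a}_{b}" for a in class_labels for b in class_labels if a != b]
    cols += ["mean_duration", "mean_occurrence", "gev", "total_time"]
    return cols


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Display rounding with ties away from zero (0.715 -> 0.72)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(round(value, ndigits + 4))).quantize(q, ROUND_HALF_UP))


def split_train_test(
    features: pd.DataFrame,
    label_col: str = "group",
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random split; test size is n * fraction rounded to nearest.

    Stratification keeps both classes represented in both partitions even
    for small cohorts, a deliberate tightening of a plain random split.
    """
    if not 0 < test_fraction < 1:
        raise InvalidArgumentError("test_fraction must be in (0, 1)")
    n = len(features)
    n_test = int(round(n * test_fraction))
    if n_test < 2 or n - n_test < 4:
        raise InvalidArgumentError("cohort too small for the requested split")
    train, test = train_test_split(
        features,
        test_size=n_test,
        stratify=features[label_col],
        random_state=seed,
    )
    counts = train[label_col].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise InvalidArgumentError("each class needs >= 2 training subjects")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def crossvalidate_tree(
    train: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "group",
    folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, DecisionTreeClassifier]:
    """Five-fold CV accuracies plus a tree refit on the full training set."""
    y = train[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("training data must contain both classes")
    X = train[feature_cols].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr_idx, va_idx in skf.split(X, y):
        tree = DecisionTreeClassifier(criterion="gini", random_state=seed)
        tree.fit(X[tr_idx], y[tr_idx])
        scores.append(accuracy_score(y[va_idx], tree.predict(X[va_idx])))
    final = DecisionTreeClassifier(criterion="gini", random_state=seed)
    final.fit(X, y)
    return np.asarray(scores), final


@dataclass
class ClassificationReport:
    """Held-out evaluation of a fitted classifier."""

    classes: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    confusion: np.ndarray
    macro: dict[str, float]
    weighted: dict[str, float]
    roc_points: np.ndarray | None  # (n_points, 2): FPR, TPR
    auc: float

    def to_frame(self) -> pd.DataFrame:
        """Report table shaped like the usual per-class summary."""
        rows = []
        for i, c in enumerate(self.classes):
            rows.append({
                "class": c,
                "precision": round_half_up(self.precision[i]),
                "recall": round_half_up(self.recall[i]),
                "f1": round_half_up(self.f1[i]),
                "support": int(self.support[i]),
            })
        n = int(self.support.sum())
        rows.append({"class": "accuracy", "precision": np.nan, "recall": np.nan,
                     "f1": round_half_up(self.accuracy), "support": n})
        for name, d in (("macro avg", self.macro), ("weighted avg", self.weighted)):
            rows.append({"class": name,
                         "precision": round_half_up(d["precision"]),
                         "recall": round_half_up(d["recall"]),
                         "f1": round_half_up(d["f1"]),
                         "support": n})
        return pd.DataFrame(rows)


def summarize_report(
    per_class: dict[str, np.ndarray],
    supports: np.ndarray,
) -> tuple[dict[str, float], dict[str, float]]:
    """Macro (unweighted) and support-weighted averages of per-class rows."""
    supports = np.asarray(supports, dtype=float)
    if supports.size == 0:
        raise InvalidArgumentError("need at least one class row")
    w = supports / supports.sum()
    macro = {k: float(np.mean(v)) for k, v in per_class.items()}
    weighted = {k: float(np.sum(w * np.asarray(v, dtype=float)))
                for k, v in per_class.items()}
    return macro, weighted


def evaluate_classifier(
    model: DecisionTreeClassifier,
    test: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "group",
    positive_class: str = "AD",
) -> ClassificationReport:
    """Confusion matrix, per-class scores, macro/weighted averages, ROC/AUC.

    ROC scores are the tree's class-probability estimates (leaf class
    fractions) for the positive class; AUC is the trapezoidal area.  With a
    single-class test set the ROC is undefined (NaN AUC) but the remaining
    metrics are still reported.
    """
    if len(test) == 0:
        raise InvalidArgumentError("test set is empty")
    y = test[label_col].to_numpy()
    X = test[feature_cols].to_numpy(dtype=float)
    classes = tuple(sorted(np.unique(np.concatenate([y, model.classes_]))))
    pred = model.predict(X)
    prec, rec, f1, sup = precision_recall_fscore_support(
        y, pred, labels=list(classes), zero_division=0)
    acc = float(accuracy_score(y, pred))
    cm = confusion_matrix(y, pred, labels=list(classes))
    macro, weighted = summarize_report(
        {"precision": prec, "recall": rec, "f1": f1}, sup)
    if len(np.unique(y)) == 2:
        pos_idx = list(model.classes_).index(positive_class)
        scores = model.predict_proba(X)[:, pos_idx]
        fpr, tpr, _ = roc_curve(y, scores, pos_label=positive_class)
        roc_points = np.column_stack([fpr, tpr])
        roc_auc = float(auc(fpr, tpr))
    else:
        warnings.warn("single-class test set; ROC undefined")
        roc_points, roc_auc = None, float("nan")
    return ClassificationReport(
        classes=classes,
        precision=prec,
        recall=rec,
        f1=f1,
        support=sup,
        accuracy=acc,
        confusion=cm,
        macro=macro,
        weighted=weighted,
        roc_points=roc_points,
        auc=roc_auc,
    )
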