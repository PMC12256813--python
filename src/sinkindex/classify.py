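"""One-vs-rest multiclass evaluation with leave-one-out cross-validation.

Every subject serves as the test set exactly once; per-fold class scores
are pooled across folds and turned into per-class one-vs-rest ROC curves
plus a micro-averaged curve whose TPR/FPR at each threshold pool the
per-class confusion counts:

    TPR = Σ_i TP_i / Σ_i (TP_i + FN_i),   FPR = Σ_j FP_j / Σ_j (FP_j + TN_j)

AUCs are trapezoidal integrals of the stored curve points. Eight classifier
families are exposed behind one interface; ROC construction always uses
continuous scores (probabilities or margins), never hard labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import label_binarize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import DegenerateInputError, ValidationError

CLASSIFIER_FAMILIES = (
    "lda", "qda", "knn", "naive_bayes", "decision_tree",
    "random_forest", "logistic_regression", "svm",
)


def make_classifier(name: str, seed: int = 0, k_neighbors: int = 2):
    """Instantiate one of the eight supported classifier families."""
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "qda":
        return QuadraticDiscriminantAnalysis()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=k_neighbors)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000)
    if name == "svm":
        return SVC(decision_function_shape="ovr")
    raise ValidationError(f"unknown classifier family {name!r}")


@dataclass
class ClassificationReport:
    classifier_name: str
    classes: list[str]
    roc_points: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auc_per_class: dict[str, float]
    micro_roc: tuple[np.ndarray, np.ndarray]
    micro_auc: float
    precision: float
    confusion: dict[str, dict[str, int]]  # class -> {TP, FP, FN, TN}
    scores: np.ndarray  # n_subjects × n_classes pooled LOOCV scores
    y_true: np.ndarray
    y_pred: np.ndarray
    seed: int
    n_folds: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier_name,
            "classes": list(self.classes),
            "auc_per_class": {k: round(v, 10) for k, v in self.auc_per_class.items()},
            "micro_auc": round(self.micro_auc, 10),
            "precision": round(self.precision, 10),
            "confusion": self.confusion,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "warnings": list(self.warnings),
        }


def loocv_splits(n: int) -> list[tuple[np.ndarray, int]]:
    """Leave-one-out splits: n iterations, each subject tested once."""
    if n < 2:
        raise DegenerateInputError("need at least 2 subjects for LOOCV")
    idx = np.arange(n)
    return [(np.delete(idx, i), i) for i in range(n)]


def _score_matrix(clf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Continuous per-class scores aligned with the global class order."""
    if hasattr(clf, "predict_proba"):
        raw = clf.predict_proba(X)
    else:
        raw = clf.decision_function(X)
        if raw.ndim == 1:  # binary margin → two-column form
            raw = np.column_stack([-raw, raw])
    out = np.full((X.shape[0], classes.size), -np.inf)
    for j, cls in enumerate(clf.classes_):
        out[:, np.searchsorted(classes, cls)] = raw[:, j]
    return out


def evaluate_ovr(
    features: np.ndarray,
    labels,
    classifier: str = "random_forest",
    seed: int = 0,
    k_neighbors: int = 2,
    estimator=None,
) -> ClassificationReport:
    """LOOCV one-vs-rest evaluation of a feature matrix.

    ``estimator`` may be any sklearn-compatible estimator (e.g. a Pipeline
    with fold-internal PCA); otherwise ``classifier`` names one of the
    eight built-in families. Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[0] == 1 and np.size(labels) > 1:
        X = X.T
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValidationError("NaN in features")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")

    base = estimator if estimator is not None else make_classifier(classifier, seed, k_neighbors)
    n = X.shape[0]
    warnings: list[str] = []
    scores = np.zeros((n, classes.size))
    y_pred = np.empty(n, dtype=y.dtype)

    degenerate = bool(np.all(X == X[0]))
    if degenerate:
        warnings.append("all-identical features; scores are uninformative (AUC 0.5)")

    if degenerate:
        # constant features carry no ranking information; fitting would be
        # ill-posed for several families, so report chance-level scores
        counts = np.array([(y == c).sum() for c in classes])
        y_pred[:] = classes[np.argmax(counts)]
    else:
        for train_idx, test_idx in loocv_splits(n):
            if np.unique(y[train_idx]).size < classes.size:
                warnings.append(f"fold {test_idx}: a class is absent from the training set")
            clf = clone(base)
            clf.fit(X[train_idx], y[train_idx])
            scores[test_idx] = _score_matrix(clf, X[test_idx : test_idx + 1], classes)[0]
            y_pred[test_idx] = classes[np.argmax(scores[test_idx])]

    y_bin = label_binarize(y, classes=classes)
    if y_bin.shape[1] == 1:  # binary case comes back single-column
        y_bin = np.column_stack([1 - y_bin[:, 0], y_bin[:, 0]])

    roc_points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    auc_per_class: dict[str, float] = {}
    confusion: dict[str, dict[str, int]] = {}
    for j, cls in enumerate(classes):
        if degenerate:
            fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
        else:
            fpr, tpr, _ = roc_curve(y_bin[:, j], scores[:, j], drop_intermediate=False)
        roc_points[str(cls)] = (fpr, tpr)
        auc_per_class[str(cls)] = float(_trapezoid_auc(fpr, tpr))
        tp = int(np.sum((y == cls) & (y_pred == cls)))
        fp = int(np.sum((y != cls) & (y_pred == cls)))
        fn = int(np.sum((y == cls) & (y_pred != cls)))
        tn = int(np.sum((y != cls) & (y_pred != cls)))
        confusion[str(cls)] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}

    if degenerate:
        micro_fpr, micro_tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
    else:
        micro_fpr, micro_tpr, _ = roc_curve(y_bin.ravel(), scores.ravel(),
                                            drop_intermediate=False)
    micro_auc = float(_trapezoid_auc(micro_fpr, micro_tpr))

    total_tp = sum(c["TP"] for c in confusion.values())
    total_fp = sum(c["FP"] for c in confusion.values())
    precision = total_tp / (total_tp + total_fp) if total_tp + total_fp else 0.0

    return ClassificationReport(
        classifier_name=(estimator.__class__.__name__ if estimator is not None else classifier),
        classes=[str(c) for c in classes],
        roc_points=roc_points,
        auc_per_class=auc_per_class,
        micro_roc=(micro_fpr, micro_tpr),
        micro_auc=micro_auc,
        precision=float(precision),
        confusion=confusion,
        scores=scores,
        y_true=y,
        y_pred=y_pred,
        seed=seed,
        n_folds=n,
        warnings=warnings,
    )


def repeated_loocv_auc(
    features: np.ndarray,
    labels,
    classifier: str = "random_forest",
    n_repeats: int = 8,
    seed: int = 0,
    k_neighbors: int = 2,
) -> dict[str, np.ndarray]:
    """Per-class AUC distributions over independent LOOCV repetitions.

    Repetitions differ only in the seed handed to stochastic classifiers;
    deterministic families yield identical repeats.
    """
    classes = [str(c) for c in np.unique(np.asarray(labels))]
    out = {cls: [] for cls in classes}
    out["micro"] = []
    for r in range(n_repeats):
        rep = evaluate_ovr(features, labels, classifier, seed=seed + r, k_neighbors=k_neighbors)
        for cls in classes:
            out[cls].append(rep.auc_per_class[cls])
        out["micro"].append(rep.micro_auc)
    return {k: np.asarray(v) for k, v in out.items()}
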