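"""Random-forest training, vote-based prediction, stratified cross-validated
evaluation with support-weighted metrics, and impurity feature ranking.

Tree growing is delegated to scikit-learn's ensemble under a fixed
contract: bootstrap per tree, Gini best-split over a random feature subset
of configurable size, trees grown until pure leaves or fewer than two
instances, fully seedable. Prediction aggregates hard per-tree votes
(not averaged leaf probabilities); importances are mean impurity decrease.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES

MODEL_FORMAT_VERSION = 1

__all__ = [
    "TrainedForest", "EvaluationReport",
    "default_features_per_split", "train_forest", "predict",
    "weighted_metrics", "cross_validate", "feature_importance",
    "correlation_baseline", "save_model", "load_model",
]


def default_features_per_split(n_features: int) -> int:
    """floor(log2(M)) + 1 candidate features per split (5 for M=22)."""
    return int(math.floor(math.log2(n_features))) + 1


@dataclass
class TrainedForest:
    """A fitted vote-aggregating forest plus its training metadata."""

    model: RandomForestClassifier
    feature_names: tuple
    n_trees: int
    features_per_split: int
    seed: int
    class_counts: dict

    @property
    def trees(self):
        return self.model.estimators_


@dataclass
class EvaluationReport:
    """Cross-validation outcome: support-weighted headline metrics plus
    per-fold detail and the pooled out-of-fold confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    roc_area: float
    per_class: dict
    confusion: list          # [[tn, fp], [fn, tp]]
    per_fold: list
    folds: int
    seed: int

    def __post_init__(self):
        for name in ("accuracy", "precision", "recall", "f_measure", "roc_area"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "roc_area": self.roc_area,
            "per_class": self.per_class,
            "confusion": self.confusion,
            "per_fold": self.per_fold,
            "folds": self.folds,
            "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    classes = set(np.unique(y))
    if classes != {0, 1}:
        raise ValueError(f"need both classes 0 and 1 in y, got {sorted(classes)}")
    return X, y


def train_forest(X, y, t: int = 100, rng_seed: int = 0, *,
                 features_per_split=None, feature_names=None,
                 bootstrap_size=None) -> TrainedForest:
    """Grow `t` trees, each on a bootstrap sample, Gini best-split over a
    random feature subset per node, until pure leaves.

    ``bootstrap_size`` optionally fixes the per-tree sample count instead
    of the default full-training-set bootstrap.
    """
    X, y = _check_xy(X, y)
    n_features = X.shape[1]
    if features_per_split is None:
        features_per_split = default_features_per_split(n_features)
    features_per_split = min(int(features_per_split), n_features)
    if feature_names is None:
        feature_names = FEATURE_NAMES if n_features == len(FEATURE_NAMES) else tuple(
            f"f{i}" for i in range(n_features))
    max_samples = None if bootstrap_size is None else min(int(bootstrap_size), len(X))
    model = RandomForestClassifier(
        n_estimators=int(t),
        criterion="gini",
        max_features=features_per_split,
        bootstrap=True,
        max_samples=max_samples,
        min_samples_split=2,
        min_samples_leaf=1,
        random_state=int(rng_seed),
        n_jobs=1,
    )
    model.fit(X, y)
    counts = {int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
    return TrainedForest(
        model=model,
        feature_names=tuple(feature_names),
        n_trees=int(t),
        features_per_split=features_per_split,
        seed=int(rng_seed),
        class_counts=counts,
    )


def predict(model: TrainedForest, X):
    """Vote aggregation: score = fraction of trees voting class 1;
    label 1 iff score > 0.5 (an exact tie goes to class 0)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, "
            f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    votes = np.stack([tree.predict(X) for tree in model.trees])
    scores = (votes == 1).mean(axis=0)
    labels = (scores > 0.5).astype(int)
    return labels, scores


def weighted_metrics(y_true, y_pred, scores=None) -> dict:
    """Accuracy, support-weighted precision/recall/F, per-class detail,
    confusion matrix, and (when scores given) trapezoidal ROC area."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    p, r, f, support = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0)
    w = support / support.sum()
    out = {
        "accuracy": float((y_true == y_pred).mean()),
        "precision": float(np.dot(w, p)),
        "recall": float(np.dot(w, r)),
        "f_measure": float(np.dot(w, f)),
        "per_class": {
            str(c): {"precision": float(p[c]), "recall": float(r[c]),
                     "f_measure": float(f[c]), "support": int(support[c])}
            for c in (0, 1)
        },
        "confusion": confusion_matrix(y_true, y_pred, labels=[0, 1]).tolist(),
    }
    if scores is not None:
        out["roc_area"] = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return out


def cross_validate(X, y, folds: int = 10, rng_seed: int = 0, *,
                   t: int = 100, features_per_split=None,
                   bootstrap_size=None) -> EvaluationReport:
    """Stratified k-fold evaluation.

    Headline metrics are computed on the pooled out-of-fold predictions
    (support-weighted over classes); per-fold metrics are also reported.
    """
    X, y = _check_xy(X, y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} instances per class for {folds}-fold "
            f"stratified CV, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng_seed))
    oof_pred = np.empty(len(y), dtype=int)
    oof_score = np.empty(len(y), dtype=float)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = train_forest(
            X[tr], y[tr], t=t, rng_seed=rng_seed + fold,
            features_per_split=features_per_split, bootstrap_size=bootstrap_size)
        labels, scores = predict(model, X[te])
        oof_pred[te] = labels
        oof_score[te] = scores
        fm = weighted_metrics(y[te], labels, scores)
        per_fold.append({"fold": fold, "n_test": int(len(te)),
                         "accuracy": fm["accuracy"],
                         "precision": fm["precision"], "recall": fm["recall"],
                         "f_measure": fm["f_measure"], "roc_area": fm["roc_area"]})
    pooled = weighted_metrics(y, oof_pred, oof_score)
    return EvaluationReport(
        accuracy=pooled["accuracy"], precision=pooled["precision"],
        recall=pooled["recall"], f_measure=pooled["f_measure"],
        roc_area=pooled["roc_area"], per_class=pooled["per_class"],
        confusion=pooled["confusion"], per_fold=per_fold,
        folds=int(folds), seed=int(rng_seed),
    )


def feature_importance(model: TrainedForest) -> list:
    """Mean Gini impurity decrease per feature, normalised to sum to 1,
    descending; ties broken by feature-column order."""
    imp = model.model.feature_importances_
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], i))
    return [(model.feature_names[i], float(imp[i])) for i in order]


def correlation_baseline(X, y, feature_names=None,
                         feature: str = "PCC_A_L1_B_L1") -> dict:
    """Single-feature |correlation| threshold baseline.

    Scores every pair by the absolute value of one correlation column and
    reports its ROC area plus the best achievable thresholded accuracy
    (an optimistic bound for any fixed-cutoff rule).
    """
    X, y = _check_xy(X, y)
    names = tuple(feature_names) if feature_names is not None else FEATURE_NAMES
    col = names.index(feature)
    scores = np.abs(X[:, col])
    order = np.argsort(scores)
    thresholds = np.concatenate(([-np.inf], scores[order]))
    best_acc = 0.0
    for thr in thresholds:
        acc = float(((scores > thr).astype(int) == y).mean())
        best_acc = max(best_acc, acc)
    return {"roc_area": float(roc_auc_score(y, scores)),
            "accuracy": best_acc, "feature": feature}


def save_model(model: TrainedForest, path) -> None:
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "model": model.model,
        "feature_names": list(model.feature_names),
        "n_trees": model.n_trees,
        "features_per_split": model.features_per_split,
        "seed": model.seed,
        "class_counts": model.class_counts,
    }, path)


def load_model(path) -> TrainedForest:
    blob = joblib.load(path)
    version = blob.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return TrainedForest(
        model=blob["model"],
        feature_names=tuple(blob["feature_names"]),
        n_trees=blob["n_trees"],
        features_per_split=blob["features_per_split"],
        seed=blob["seed"],
        class_counts=blob["class_counts"],
    )
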