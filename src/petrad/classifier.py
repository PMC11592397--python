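"""One-year survival classification with a balanced random forest.

Each tree trains on a bootstrap that draws (with replacement) the minority
class size from *both* classes, so every tree sees a balanced sample.
Hyperparameters come from a 5-fold cross-validated grid search scored by AUC.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "BRFConfig",
    "ConfusionMetrics",
    "BalancedRandomForest",
    "balanced_bootstrap",
    "fit_brf",
    "evaluate",
    "reconstruct_confusion_matrices",
]

log = logging.getLogger(__name__)


def balanced_bootstrap(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-tree sample indices: draw with replacement ``n_min`` from each class,
    where ``n_min`` is the minority class size; class counts are equal by
    construction."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("balanced bootstrap requires both classes present")
    n_min = int(counts.min())
    picks = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        picks.append(rng.choice(idx, size=n_min, replace=True))
    return np.concatenate(picks)


class BalancedRandomForest:
    """Random forest over balanced bootstraps (scikit-learn tree base learners)."""

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        min_samples_split: int = 2,
        min_samples_leaf: int = 1,
        max_features="sqrt",
        bootstrap: bool = True,
        criterion: str = "gini",
        random_state: int = 0,
    ):
        if n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.criterion = criterion
        self.random_state = random_state
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None

    def get_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "min_samples_leaf": self.min_samples_leaf,
            "max_features": self.max_features,
            "bootstrap": self.bootstrap,
            "criterion": self.criterion,
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training labels contain a single class")
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        self.bootstrap_indices_ = []
        for t in range(self.n_estimators):
            if self.bootstrap:
                idx = balanced_bootstrap(y, rng)
            else:
                idx = np.arange(y.size)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                max_features=self.max_features,
                criterion=self.criterion,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.bootstrap_indices_.append(idx)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        probs = np.zeros((X.shape[0], self.classes_.size))
        for tree in self.trees_:
            p = tree.predict_proba(X)
            # align tree classes to forest classes
            for ci, c in enumerate(tree.classes_):
                probs[:, np.searchsorted(self.classes_, c)] += p[:, ci]
        return probs / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class BRFConfig:
    """Hyperparameter grids for the balanced-random-forest grid search."""

    max_depth: tuple = (3, 5, None)
    n_estimators: tuple = (100, 300)
    min_samples_split: tuple = (2, 5)
    min_samples_leaf: tuple = (1, 3)
    max_features: tuple = ("sqrt", 0.5)
    bootstrap: tuple = (True,)
    criterion: tuple = ("gini", "entropy")
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_depth", "n_estimators", "min_samples_split",
                     "min_samples_leaf", "max_features", "bootstrap", "criterion"):
            if not getattr(self, name):
                raise ValueError(f"empty grid for {name}")
        if any(n < 1 for n in self.n_estimators):
            raise ValueError("n_estimators must be >= 1")

    def grid(self):
        keys = ("max_depth", "n_estimators", "min_samples_split", "min_samples_leaf",
                "max_features", "bootstrap", "criterion")
        for combo in itertools.product(*(getattr(self, k) for k in keys)):
            yield dict(zip(keys, combo))


def fit_brf(X: np.ndarray, y: np.ndarray, config: BRFConfig) -> tuple[BalancedRandomForest, dict]:
    """Grid search (stratified K-fold, mean AUC) then refit on the full set.

    Returns the fitted forest and a report with the chosen hyperparameters and
    the CV AUC table.  Deterministic under ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    folds = min(config.cv_folds, int(counts.min()))
    if folds < 2:
        raise ValueError("too few minority-class subjects for cross-validation")
    if folds < config.cv_folds:
        log.warning("fit_brf: reduced CV folds to %d (minority class size)", folds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    splits = list(cv.split(X, y))

    results = []
    best_auc, best_params = -np.inf, None
    for params in config.grid():
        aucs = []
        for tr, te in splits:
            model = BalancedRandomForest(random_state=config.seed, **params)
            model.fit(X[tr], y[tr])
            proba = model.predict_proba(X[te])[:, -1]
            aucs.append(roc_auc_score(y[te], proba))
        mean_auc = float(np.mean(aucs))
        results.append({"params": params, "cv_auc": mean_auc})
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    model = BalancedRandomForest(random_state=config.seed, **best_params)
    model.fit(X, y)
    return model, {"best_params": best_params, "best_cv_auc": best_auc, "cv_table": results}


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    auc: float | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        self.sensitivity = self.tp / pos if pos else float("nan")
        self.specificity = self.tn / neg if neg else float("nan")
        self.accuracy = (self.tp + self.tn) / (pos + neg)

    def as_dict(self, ndigits: int = 2) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "accuracy": round(self.accuracy, ndigits),
            "auc": round(self.auc, ndigits) if self.auc is not None else None,
        }


def evaluate(
    model: BalancedRandomForest, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[ConfusionMetrics, np.ndarray]:
    """Test-set confusion metrics at probability threshold 0.5 plus ROC points.

    The positive class is the larger label (deceased at 1 year = 1)."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=int)
    if np.unique(y_test).size < 2:
        raise ValueError("test set contains a single class; AUC undefined")
    proba = model.predict_proba(X_test)[:, -1]
    pred = (proba >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    metrics = ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
    metrics.auc = float(roc_auc_score(y_test, proba))
    fpr, tpr, thresholds = roc_curve(y_test, proba)
    roc_points = np.column_stack([fpr, tpr, thresholds])
    return metrics, roc_points


def reconstruct_confusion_matrices(
    printed: dict[str, tuple[float, float]], n_total: int, ndigits: int = 2
) -> dict[str, ConfusionMetrics]:
    """Recover the integer confusion matrices behind printed sensitivity /
    specificity values that share one test-set class split.

    Enumerates every positive-class size ``P`` and integer (TP, TN) per model;
    keeps splits where all models' rates round to the printed values
    simultaneously.  Raises unless the split is unique.
    """
    solutions = []
    for pos in range(1, n_total):
        neg = n_total - pos
        per_model = {}
        for name, (sens, spec) in printed.items():
            tps = [tp for tp in range(pos + 1) if round(tp / pos, ndigits) == sens]
            tns = [tn for tn in range(neg + 1) if round(tn / neg, ndigits) == spec]
            if not tps or not tns:
                per_model = None
                break
            if len(tps) > 1 or len(tns) > 1:
                per_model = None  # ambiguous within a model: reject this split
                break
            per_model[name] = (tps[0], tns[0])
        if per_model:
            solutions.append((pos, per_model))
    if len(solutions) != 1:
        raise ValueError(
            f"confusion-matrix reconstruction not unique: {len(solutions)} candidate splits"
        )
    pos, per_model = solutions[0]
    neg = n_total - pos
    return {
        name: ConfusionMetrics(tp=tp, fp=neg - tn, tn=tn, fn=pos - tp)
        for name, (tp, tn) in per_model.items()
    }
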