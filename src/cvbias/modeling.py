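"""Feature scoring, top-k selection, classifier training, and metrics.

This is the standard tabular-radiomics pipeline: score every feature for
relevance, keep the k best, fit a classifier, and evaluate probabilistic
predictions with AUC, sensitivity, specificity, balanced accuracy, and the
Brier score.  Everything operates on already z-scored features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import LabeledTable

__all__ = [
    "ModelGrid",
    "MetricSet",
    "anova_score",
    "bhattacharyya_score",
    "extratrees_score",
    "lasso_score",
    "score_features",
    "select_top_k",
    "train_predict",
    "evaluate",
]

#: cap for infinite F statistics (zero within-class variance) so that
#: ranking stays well defined
_F_CAP = 1e12
_VAR_FLOOR = 1e-12

SCORERS = ("anova", "bhattacharyya", "extra_trees", "lasso")
CLASSIFIERS = ("logistic_regression", "naive_bayes", "rbf_svm", "random_forest", "knn")


def _pow2_grid(lo=-10, hi=10) -> tuple:
    return tuple(float(2.0**e) for e in range(lo, hi + 1))


@dataclass(frozen=True)
class ModelGrid:
    """The model search space: scorers x top-k counts x classifiers x
    classifier hyperparameter grids.

    Defaults are the full grid (k-NN off by default — it sits in the
    hyperparameter table but not among the four classifiers actually used);
    :meth:`reduced` gives a small grid for quick runs and CI.
    """

    scorers: tuple = SCORERS
    n_features_grid: tuple = (1, 2, 4, 8, 16, 32, 64)
    classifiers: tuple = ("logistic_regression", "naive_bayes", "rbf_svm", "random_forest")
    lr_C_grid: tuple = field(default_factory=_pow2_grid)
    svm_C_grid: tuple = field(default_factory=_pow2_grid)
    rf_n_trees: int = 250
    knn_k_grid: tuple = (1, 3, 5, 7, 9)
    lasso_C: float = 1.0

    def __post_init__(self):
        for s in self.scorers:
            if s not in SCORERS:
                raise ValueError(f"unknown scorer {s!r}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")
        if not (self.scorers and self.n_features_grid and self.classifiers):
            raise ValueError("scorers, n_features_grid and classifiers must be nonempty")

    @classmethod
    def reduced(cls) -> "ModelGrid":
        """Small search space for scaled-down runs: 2 scorers x {1,4,16}
        features x 2 classifiers x coarse C grid."""
        return cls(
            scorers=("anova", "bhattacharyya"),
            n_features_grid=(1, 4, 16),
            classifiers=("logistic_regression", "naive_bayes"),
            lr_C_grid=(0.01, 1.0, 100.0),
        )

    def configs(self):
        """Deterministic enumeration of (scorer, n_features, classifier,
        hyperparams); tie-breaks in best-model selection follow this order."""
        for scorer in self.scorers:
            for k in self.n_features_grid:
                for clf in self.classifiers:
                    for hp in self._hyperparams(clf):
                        yield scorer, int(k), clf, hp

    def _hyperparams(self, clf: str):
        if clf == "logistic_regression":
            return [{"C": c} for c in self.lr_C_grid]
        if clf == "naive_bayes":
            return [{}]
        if clf == "rbf_svm":
            return [{"C": c, "gamma": "auto"} for c in self.svm_C_grid]
        if clf == "random_forest":
            return [{"n_estimators": self.rf_n_trees}]
        if clf == "knn":
            return [{"n_neighbors": k} for k in self.knn_k_grid]
        raise ValueError(clf)


@dataclass(frozen=True)
class MetricSet:
    """The five evaluation metrics of one model on one test set (or their
    fold-mean, or — via subtraction — a per-metric bias)."""

    auc: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    brier: float

    def __sub__(self, other: "MetricSet") -> "MetricSet":
        return MetricSet(
            self.auc - other.auc,
            self.sensitivity - other.sensitivity,
            self.specificity - other.specificity,
            self.balanced_accuracy - other.balanced_accuracy,
            self.brier - other.brier,
        )

    @staticmethod
    def mean(sets) -> "MetricSet":
        sets = list(sets)
        return MetricSet(
            *(float(np.mean([getattr(s, f) for s in sets]))
              for f in ("auc", "sensitivity", "specificity", "balanced_accuracy", "brier"))
        )

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "brier": self.brier,
        }


# ------------------------------------------------------------- scorers

def _check_classes(labels):
    vals, counts = np.unique(labels, return_counts=True)
    if len(vals) != 2 or counts.min() < 2:
        raise ValueError("scoring requires two classes with >= 2 samples each")


def anova_score(features, labels) -> np.ndarray:
    """One-way ANOVA F statistic per feature; higher = more class-relevant.

    Constant features score 0; infinite F (zero within-class variance with a
    between-class difference) is capped at 1e12 so it still ranks first.
    """
    _check_classes(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(np.asarray(features, dtype=float), np.asarray(labels))
    F = np.nan_to_num(F, nan=0.0, posinf=_F_CAP)
    return np.minimum(F, _F_CAP)


def bhattacharyya_score(features, labels) -> np.ndarray:
    """Bhattacharyya distance between the class-conditional Gaussians of
    each feature:

        BD = 1/4 (mu1-mu0)^2/(s0^2+s1^2) + 1/2 ln((s0^2+s1^2)/(2 s0 s1))

    Variances are floored at 1e-12 so constant features score 0 instead of
    erroring.  Symmetric under class swap.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_classes(y)
    X0, X1 = X[y == np.unique(y)[0]], X[y == np.unique(y)[1]]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    v0 = np.maximum(X0.var(axis=0), _VAR_FLOOR)
    v1 = np.maximum(X1.var(axis=0), _VAR_FLOOR)
    return 0.25 * (m1 - m0) ** 2 / (v0 + v1) + 0.5 * np.log(
        (v0 + v1) / (2.0 * np.sqrt(v0 * v1))
    )


def extratrees_score(features, labels, seed: int = 0) -> np.ndarray:
    """Impurity-based importances of a 100-tree extremely-randomized-trees
    ensemble; nonnegative, summing to 1 (uniform if the forest is degenerate)."""
    _check_classes(labels)
    et = ExtraTreesClassifier(n_estimators=100, random_state=seed)
    et.fit(np.asarray(features, dtype=float), np.asarray(labels))
    imp = et.feature_importances_
    if imp.sum() == 0:
        imp = np.full_like(imp, 1.0 / len(imp))
    return imp


def lasso_score(features, labels, C: float = 1.0) -> np.ndarray:
    """Absolute coefficients of an L1-penalized logistic regression
    (inverse-regularization C); zeroed-out features rank last."""
    _check_classes(labels)
    model = LogisticRegression(
        penalty="l1", C=C, solver="liblinear", max_iter=5000, random_state=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(np.asarray(features, dtype=float), np.asarray(labels))
    return np.abs(model.coef_.ravel())


def score_features(table: LabeledTable, scorer: str, seed: int = 0, lasso_C: float = 1.0) -> np.ndarray:
    if scorer == "anova":
        return anova_score(table.features, table.labels)
    if scorer == "bhattacharyya":
        return bhattacharyya_score(table.features, table.labels)
    if scorer == "extra_trees":
        return extratrees_score(table.features, table.labels, seed=seed)
    if scorer == "lasso":
        return lasso_score(table.features, table.labels, C=lasso_C)
    raise ValueError(f"unknown scorer {scorer!r}")


def select_top_k(scores, k: int) -> np.ndarray:
    """Indices of the k highest scores; ties broken by lowest index; k is
    clamped to the number of features."""
    scores = np.asarray(scores, dtype=float)
    k = min(int(k), len(scores))
    return np.argsort(-scores, kind="stable")[:k]


# ---------------------------------------------------------- classifiers

def _make_classifier(name: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams)
    if name == "logistic_regression":
        return LogisticRegression(
            C=hp.get("C", 1.0), solver="liblinear", max_iter=5000, random_state=seed
        )
    if name == "naive_bayes":
        return GaussianNB()
    if name == "rbf_svm":
        # probability=True fits Platt scaling on an internal CV so the Brier
        # score sees calibrated probabilities; AUC uses the same outputs
        return SVC(
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "auto"),
            kernel="rbf",
            probability=True,
            random_state=seed,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 250), random_state=seed
        )
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    raise ValueError(f"unknown classifier {name!r}")


def train_predict(
    train: LabeledTable,
    test_features,
    classifier: str,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fit one classifier on ``train`` and return positive-class (label 1)
    probabilities for ``test_features``.

    gamma="auto" for the RBF-SVM means 1/d.  The training fold must contain
    both classes (stratified splitting upstream guarantees this).
    """
    counts = train.class_counts()
    if len(counts) < 2:
        raise ValueError("training fold contains a single class")
    clf = _make_classifier(classifier, hyperparams or {}, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(train.features, train.labels)
        probs = clf.predict_proba(np.asarray(test_features, dtype=float))
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return probs[:, pos_col]


def evaluate(probs, labels, threshold: float = 0.5) -> MetricSet:
    """All five metrics of a probability vector against binary labels.

    AUC is the rank statistic (midranks for ties); for binary outcomes the
    macro-averaged AUC coincides with it.  Sensitivity and specificity use
    ``prob >= threshold`` as the positive call; balanced accuracy is their
    mean; Brier is mean((prob - label)^2).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    auc = float(roc_auc_score(y, probs))
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    brier = float(np.mean((probs - y) ** 2))
    return MetricSet(auc, sens, spec, (sens + spec) / 2.0, brier)
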