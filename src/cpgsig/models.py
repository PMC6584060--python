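"""The four classifier families, per-fold family selection, hidden evaluation.

Families follow a Weka-style setup: a CART decision tree (DT), an
L2-regularized logistic regression (LR), a radial-basis-function network (RBF:
per-class k-means centers, Gaussian activations, logistic output layer), and a
multilayer perceptron (MLP) with two hidden layers of ten logistic units
trained by full-batch SGD with momentum. For each fold all four families are
fitted on the training cohort; the family with the highest cross-validation
accuracy is selected (ties resolved by the fixed preference MLP > LR > DT >
RBF) and only that model is scored on the hidden cohort, which no fitting or
selection step ever touches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from ._seeds import child_seed
from .io import ALLERGIC, SENSITIZED, BetaMatrix, LabeledCohort
from .folds import Fold

FAMILIES = ("DT", "LR", "RBF", "MLP")
# preference order used when cross-validation accuracies tie
TIE_ORDER = ("MLP", "LR", "DT", "RBF")


class DegenerateTrainingError(ValueError):
    """Training labels contain a single class."""


class UndefinedAUROCError(ValueError):
    """AUROC is undefined when only one class is present."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the four families; defaults follow Weka conventions.

    Every value is config-visible and overridable; none is privileged.
    """

    mlp_hidden: tuple = (10, 10)
    mlp_max_iter: int = 500
    mlp_learning_rate: float = 0.3
    mlp_momentum: float = 0.2
    dt_min_samples_leaf: int = 2
    lr_c: float = 1.0
    rbf_centers_per_class: int = 2
    rbf_width_floor: float = 1e-3
    rbf_kmeans_n_init: int = 2


DEFAULT_CONFIG = ModelConfig()


class _RBFNetwork:
    """RBF network: per-class k-means centers, Gaussian basis, logistic output."""

    def __init__(self, centers_per_class=2, width_floor=1e-3, n_init=2, seed=0):
        self.centers_per_class = centers_per_class
        self.width_floor = width_floor
        self.n_init = n_init
        self.seed = seed

    def fit(self, X, y):
        centers, widths = [], []
        for cls in (0, 1):
            Xc = X[y == cls]
            k = min(self.centers_per_class, len(np.unique(Xc, axis=0)))
            km = KMeans(n_clusters=k, n_init=self.n_init, random_state=self.seed).fit(Xc)
            for j in range(k):
                members = Xc[km.labels_ == j]
                center = km.cluster_centers_[j]
                rms = np.sqrt(np.mean(np.sum((members - center) ** 2, axis=1)))
                centers.append(center)
                widths.append(max(rms, self.width_floor))
        self.centers_ = np.asarray(centers)
        self.widths_ = np.asarray(widths)
        self.out_ = LogisticRegression(max_iter=1000).fit(self._phi(X), y)
        return self

    def _phi(self, X):
        d2 = ((X[:, None, :] - self.centers_[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths_**2))

    def predict_proba(self, X):
        return self.out_.predict_proba(self._phi(X))


@dataclass
class TrainedClassifier:
    """A fitted model of one family on a fixed ordered CpG feature subset."""

    family: str
    features: tuple
    estimator: object
    seed: int

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Probability of the allergic class for each row of X."""
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        return np.clip(proba[:, 1], 0.0, 1.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels at the 0.5 probability threshold (ties -> allergic)."""
        score = self.predict_score(X)
        return np.where(score >= 0.5, ALLERGIC, SENSITIZED)


def _encode(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1 if l == ALLERGIC else 0 for l in labels], dtype=int)


def fit(
    family: str,
    features: Sequence[str],
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    sample_ids: Sequence[str],
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
) -> TrainedClassifier:
    """Fit one family on the given training samples. Deterministic given seed."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    features = tuple(features)
    X = matrix.sample_array(features, sample_ids)
    y = _encode([cohort.label_of[s] for s in sample_ids])
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")

    if family == "DT":
        est = DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=config.dt_min_samples_leaf,
            random_state=seed,
        ).fit(X, y)
    elif family == "LR":
        est = LogisticRegression(C=config.lr_c, max_iter=1000).fit(X, y)
    elif family == "RBF":
        est = _RBFNetwork(
            centers_per_class=config.rbf_centers_per_class,
            width_floor=config.rbf_width_floor,
            n_init=config.rbf_kmeans_n_init,
            seed=seed,
        ).fit(X, y)
    else:  # MLP
        est = MLPClassifier(
            hidden_layer_sizes=config.mlp_hidden,
            activation="logistic",
            solver="sgd",
            learning_rate="constant",
            learning_rate_init=config.mlp_learning_rate,
            momentum=config.mlp_momentum,
            nesterovs_momentum=False,
            batch_size=len(y),  # full batch
            max_iter=config.mlp_max_iter,
            tol=0.0,  # no early stopping: always run the full epoch budget
            n_iter_no_change=config.mlp_max_iter,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
    return TrainedClassifier(family, features, est, seed)


def accuracy(predicted: Sequence[str], truth: Sequence[str]) -> float:
    predicted = list(predicted)
    truth = list(truth)
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def auroc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Mann-Whitney AUROC of allergic-class scores; ties contribute 1/2."""
    y = _encode(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUROCError("both classes must be present")
    ranks = rankdata(np.asarray(scores, dtype=float))
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class FoldEvaluation:
    """Outcome of family selection and hidden scoring on one fold."""

    fold_index: int
    selected_family: str
    cv_accuracy: float
    hidden_accuracy: float
    hidden_auroc: float
    cv_accuracies: dict = field(default_factory=dict, compare=False)
    hidden_sample_ids: tuple = field(default=(), compare=False)
    hidden_predictions: tuple = field(default=(), compare=False)
    hidden_scores: tuple = field(default=(), compare=False)


def evaluations_frame(evaluations: Sequence["FoldEvaluation"]):
    """Tabulate fold evaluations (one row per fold) for TSV serialization."""
    import pandas as pd

    return pd.DataFrame(
        {
            "fold_index": [e.fold_index for e in evaluations],
            "selected_family": [e.selected_family for e in evaluations],
            "cv_accuracy": [e.cv_accuracy for e in evaluations],
            "hidden_accuracy": [e.hidden_accuracy for e in evaluations],
            "hidden_auroc": [e.hidden_auroc for e in evaluations],
        }
    )


def select_and_evaluate(
    features: Sequence[str],
    fold: Fold,
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
) -> FoldEvaluation:
    """Fit all four families on train, pick by cv accuracy, score on hidden."""
    train, cv, hidden = fold.train, fold.cv, fold.hidden
    if not (train and cv and hidden):
        raise ValueError("fold must supply non-empty train/cv/hidden cohorts")
    assert not (set(train) & set(cv)) and not (set(train) & set(hidden)) and not (
        set(cv) & set(hidden)
    ), "fold cohorts must be disjoint"

    features = tuple(features)
    X_cv = matrix.sample_array(features, cv)
    y_cv = [cohort.label_of[s] for s in cv]
    fitted, cv_acc = {}, {}
    for family in FAMILIES:
        clf = fit(family, features, matrix, cohort, train, child_seed(seed, family), config)
        fitted[family] = clf
        cv_acc[family] = accuracy(clf.predict(X_cv), y_cv)

    best = max(TIE_ORDER, key=lambda f: (cv_acc[f], -TIE_ORDER.index(f)))
    chosen = fitted[best]

    X_h = matrix.sample_array(features, hidden)
    y_h = [cohort.label_of[s] for s in hidden]
    scores = chosen.predict_score(X_h)
    preds = chosen.predict(X_h)
    return FoldEvaluation(
        fold_index=fold.index,
        selected_family=best,
        cv_accuracy=cv_acc[best],
        hidden_accuracy=accuracy(preds, y_h),
        hidden_auroc=auroc(scores, y_h),
        cv_accuracies=dict(cv_acc),
        hidden_sample_ids=tuple(hidden),
        hidden_predictions=tuple(preds),
        hidden_scores=tuple(float(s) for s in scores),
    )
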