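"""One-versus-one multiclass soft-margin SVM with RBF kernel.

For k identity classes, k(k-1)/2 binary soft-margin classifiers are trained,
one per unordered class pair, each seeing only that pair's training rows.  A
test beat is voted on by every sub-classifier ("plus one" to the winning
class); the class with the highest accumulated score wins, with ties broken
by the largest sum of signed decision margins and finally by the lowest
label.  The binary quadratic-program solver is scikit-learn's ``SVC``
(libsvm); this module owns the pairwise construction, the voting rule, the
kernel definition and the cross-validation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import Dataset

__all__ = ["SVMConfig", "OVOModel", "rbf_kernel", "train_ovo", "predict_ovo", "cross_validate"]


@dataclass(frozen=True)
class SVMConfig:
    """Penalty c, RBF width g and kernel choice."""

    c: float = 10.0
    g: float = 2.0
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("penalty parameter c must be > 0")
        if self.kernel == "rbf" and self.g <= 0:
            raise ValueError("RBF hyperparameter g must be > 0")
        if self.kernel not in ("linear", "poly", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def rbf_kernel(x: np.ndarray, y: np.ndarray, g: float) -> float:
    """Gaussian kernel K(x, y) = exp(-g * ||x - y||^2), in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if g < 0:
        raise ValueError("g must be >= 0")
    return float(np.exp(-g * np.sum((x - y) ** 2)))


def _make_svc(config: SVMConfig) -> SVC:
    kernel = "poly" if config.kernel == "polynomial" else config.kernel
    gamma = config.g if kernel in ("rbf", "poly") else "scale"
    return SVC(C=config.c, kernel=kernel, gamma=gamma, degree=3)


@dataclass
class OVOModel:
    """k(k-1)/2 fitted pairwise classifiers plus the class list."""

    classes: np.ndarray
    classifiers: dict[tuple, SVC]
    config: SVMConfig

    def __post_init__(self) -> None:
        k = len(self.classes)
        if len(self.classifiers) != k * (k - 1) // 2:
            raise ValueError("expected one classifier per unordered class pair")


def train_ovo(
    dataset: Dataset | tuple[np.ndarray, np.ndarray], config: SVMConfig | None = None
) -> OVOModel:
    """Fit one binary classifier per class pair on that pair's rows only."""
    config = config or SVMConfig()
    if isinstance(dataset, Dataset):
        X, y = dataset.X_train, dataset.y_train
    else:
        X, y = dataset
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int(np.sum(y == c)) for c in classes}
    empty = [c for c, n in counts.items() if n < 1]
    if empty:
        raise ValueError(f"classes without training rows: {empty}")
    classifiers: dict[tuple, SVC] = {}
    for a, b in combinations(classes, 2):
        rows = (y == a) | (y == b)
        clf = _make_svc(config)
        clf.fit(X[rows], y[rows])
        classifiers[(a, b)] = clf
    return OVOModel(classes=classes, classifiers=classifiers, config=config)


def predict_ovo(model: OVOModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over all pairwise classifiers.

    Ties are resolved by the largest accumulated signed decision margin,
    then by the lowest class label, so prediction is deterministic and
    independent of the order in which sub-classifiers vote.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = model.classes
    pos = {c: i for i, c in enumerate(classes)}
    votes = np.zeros((len(X), len(classes)))
    margins = np.zeros((len(X), len(classes)))
    for (a, b), clf in model.classifiers.items():
        # decision_function is signed towards the second class of the pair
        d = clf.decision_function(X)
        second = clf.classes_[1]
        first = clf.classes_[0]
        winner_is_second = d > 0
        for cls, won, sign in ((second, winner_is_second, 1.0), (first, ~winner_is_second, -1.0)):
            votes[won, pos[cls]] += 1
            margins[:, pos[cls]] += sign * d
    # lexicographic: votes, then margin, then lowest label (classes sorted)
    best = np.zeros(len(X), dtype=int)
    for i in range(len(X)):
        order = np.lexsort((np.arange(len(classes)), -margins[i], -votes[i]))
        best[i] = order[0]
    return classes[best]


def cross_validate(
    features: np.ndarray,
    labels: Sequence,
    folds: int = 3,
    config: SVMConfig | None = None,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy over stratified folds; deterministic per seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` rows")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        model = train_ovo((X[train], y[train]), config)
        pred = predict_ovo(model, X[test])
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs))
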