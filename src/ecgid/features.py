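"""Beat-level fiducial features and dataset assembly.

Each delineated beat is summarised by 22 numbers: 16 inter-landmark time
intervals (seconds) and 6 amplitude differences (mV).  Intervals are
fs-independent; amplitude features are differences, so they are invariant to
any DC offset of the record.  The feature matrix, per-subject labels, a
stratified train/test split and train-fitted z-score normalisation make up a
``Dataset`` ready for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fiducials import BeatFiducials

__all__ = [
    "INTERVAL_FEATURES",
    "AMPLITUDE_FEATURES",
    "FEATURE_NAMES",
    "FeatureVector",
    "Dataset",
    "extract_features",
    "features_to_frame",
    "split_dataset",
]

INTERVAL_FEATURES: tuple[tuple[str, str], ...] = (
    ("R", "R"),  # to next beat's R
    ("R", "Q"),
    ("R", "S"),
    ("R", "P"),
    ("R", "T"),
    ("R", "PBegin"),
    ("R", "PEnd"),
    ("R", "TBegin"),
    ("R", "TEnd"),
    ("Q", "P"),
    ("Q", "PBegin"),
    ("S", "T"),
    ("S", "TEnd"),
    ("P", "T"),
    ("PBegin", "PEnd"),
    ("TBegin", "TEnd"),
)
AMPLITUDE_FEATURES: tuple[tuple[str, str], ...] = (
    ("R", "Q"),
    ("R", "S"),
    ("Q", "P"),
    ("S", "T"),
    ("PBegin", "P"),
    ("TBegin", "T"),
)
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"int_{a}_{b}" for a, b in INTERVAL_FEATURES
) + tuple(f"amp_{a}_{b}" for a, b in AMPLITUDE_FEATURES)


@dataclass(frozen=True)
class FeatureVector:
    """One beat's 22-dimensional descriptor plus its subject label."""

    values: np.ndarray
    subject: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (22,):
            raise ValueError(f"expected 22 features, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("features must be finite")
        if np.any(v[: len(INTERVAL_FEATURES)] <= 0):
            raise ValueError("interval features must be positive")
        object.__setattr__(self, "values", v)


def extract_features(
    fiducials: Sequence[BeatFiducials], fs: float, subject: int = 0
) -> list[FeatureVector]:
    """22 features per beat; the last beat is dropped (no R-R successor).

    Interval feature X-Y is ``|index(X) - index(Y)| / fs`` within the beat
    (R-R spans to the next beat's R); amplitude feature X-Y is
    ``amplitude(X) - amplitude(Y)``.
    """
    if len(fiducials) < 2:
        import warnings

        warnings.warn("need at least 2 beats for R-R; returning no features")
        return []
    out: list[FeatureVector] = []
    for beat, nxt in zip(fiducials[:-1], fiducials[1:]):
        vals = [(nxt.R - beat.R) / fs]
        vals += [beat.interval(a, b) for a, b in INTERVAL_FEATURES[1:]]
        vals += [beat.amplitudes[a] - beat.amplitudes[b] for a, b in AMPLITUDE_FEATURES]
        out.append(FeatureVector(values=np.array(vals), subject=subject))
    return out


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors with a trailing ``subject`` column."""
    df = pd.DataFrame(
        [f.values for f in features], columns=list(FEATURE_NAMES)
    )
    df["subject"] = [f.subject for f in features]
    return df


@dataclass
class Dataset:
    """Split, z-scored feature matrix with aligned labels.

    Normalisation statistics are fitted on the training rows only and applied
    to both splits; raw (unnormalised) matrices are retained for inspection.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y_train))


def split_dataset(
    features: np.ndarray | Sequence[FeatureVector],
    labels: Sequence[int] | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
    normalize: bool = True,
) -> Dataset:
    """Stratified-by-subject random split with train-fitted z-scoring.

    Every subject contributes ``train_fraction`` of its beats (rounded) to
    the training rows, so all classes appear in both splits.  Deterministic
    for a fixed seed.
    """
    if labels is None:
        fv = list(features)
        X = np.array([f.values for f in fv])
        y = np.array([f.subject for f in fv])
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        if len(rows) < 2:
            raise ValueError(f"subject {cls!r} has fewer than 2 beats; cannot stratify")
        rows = rng.permutation(rows)
        n_train = int(round(train_fraction * len(rows)))
        n_train = min(max(n_train, 1), len(rows) - 1)
        train_idx.extend(rows[:n_train])
        test_idx.extend(rows[n_train:])
    train = np.sort(np.array(train_idx))
    test = np.sort(np.array(test_idx))
    X_train, X_test = X[train], X[test]
    if normalize:
        mean = X_train.mean(axis=0)
        std = X_train.std(axis=0)
        std[std == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    return Dataset(
        X_train=(X_train - mean) / std,
        y_train=y[train],
        X_test=(X_test - mean) / std,
        y_test=y[test],
        mean=mean,
        std=std,
        train_idx=train,
        test_idx=test,
    )
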