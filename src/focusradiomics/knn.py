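"""3-nearest-neighbour classifier with the discrete P(+) probability rule.

The positive-class probability of a query is determined by the classes of
its three nearest training neighbours (Euclidean distance on z-scored
features) and can take only the values {0, 0.33, 0.66, 1}; a case is called
positive when P(+) exceeds the 0.5 threshold, which for k = 3 is exactly the
unweighted majority vote.  Exact distance ties are broken by lowest
training-case index, making predictions deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: printed P(+) values for k = 3, indexed by the number of positive neighbours
PPLUS_K3 = {0: 0.0, 1: 0.33, 2: 0.66, 3: 1.0}

POSITIVE_LABEL = "malignant"


@dataclass
class KnnModel:
    X: np.ndarray                 # (n, p) z-scored training features
    y: np.ndarray                 # (n,) bool, True = positive class
    mu: np.ndarray
    sd: np.ndarray
    k: int
    feature_names: list | None = None
    keep: np.ndarray | None = None   # columns of the raw input that survived


@dataclass
class Prediction:
    p_positive: float
    predicted_class: str
    neighbour_ids: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_matrix(features, feature_names=None):
    if isinstance(features, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in features.columns]
            if missing:
                raise ValueError(f"feature names missing from input: {missing[:5]}")
            features = features[feature_names]
        names = list(features.columns)
        return features.to_numpy(dtype=float), names
    arr = np.atleast_2d(np.asarray(features, dtype=float))
    if feature_names is not None and arr.shape[1] != len(feature_names):
        raise ValueError("feature count mismatch with training set")
    return arr, feature_names


def _as_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return np.asarray([str(l) == POSITIVE_LABEL for l in labels])


def fit(features, labels, k: int = 3) -> KnnModel:
    """Store z-score normalisation and the normalised training matrix.

    Constant features (zero training SD) are dropped with a warning; an
    error is raised if none remain, if k exceeds the number of training
    cases, or if the training set lacks one of the two classes.
    """
    X, names = _as_matrix(features)
    y = _as_labels(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} training cases")
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)")
        if not keep.any():
            raise ValueError("all features are constant in the training set")
        X = X[:, keep]
        mu, sd = mu[keep], sd[keep]
        if names is not None:
            names = [n for n, kp in zip(names, keep) if kp]
    return KnnModel((X - mu) / sd, y, mu, sd, int(k), names, keep)


def _neighbours(model: KnnModel, features) -> np.ndarray:
    Xq, _ = _as_matrix(features, model.feature_names)
    if (Xq.shape[1] != model.X.shape[1] and model.keep is not None
            and Xq.shape[1] == len(model.keep)):
        Xq = Xq[:, model.keep]      # drop the columns fit() dropped
    if Xq.shape[1] != model.X.shape[1]:
        raise ValueError("feature count mismatch with training set")
    Xq = (Xq - model.mu) / model.sd
    d2 = ((Xq[:, None, :] - model.X[None, :, :]) ** 2).sum(axis=-1)
    # stable sort on distance -> exact ties broken by lowest training index
    return np.argsort(d2, axis=1, kind="stable")[:, :model.k]


def predict_proba(model: KnnModel, features) -> np.ndarray:
    """Discrete P(+) per query; for k = 3 the printed values {0, 0.33,
    0.66, 1} according to how many of the 3 nearest neighbours are
    positive."""
    nbr = _neighbours(model, features)
    votes = model.y[nbr].sum(axis=1)
    if model.k == 3:
        return np.array([PPLUS_K3[int(v)] for v in votes])
    return votes / float(model.k)


def predict(model: KnnModel, features, threshold: float = 0.5) -> list:
    """Class calls: positive iff P(+) > threshold (majority vote at 0.5)."""
    nbr = _neighbours(model, features)
    votes = model.y[nbr].sum(axis=1)
    if model.k == 3:
        probs = np.array([PPLUS_K3[int(v)] for v in votes])
    else:
        probs = votes / float(model.k)
    return [Prediction(float(p), POSITIVE_LABEL if p > threshold else "benign",
                       nbr[i])
            for i, p in enumerate(probs)]


def knn_vote_scores(X_train: np.ndarray, y_train: np.ndarray,
                    X_test: np.ndarray, y_test: np.ndarray,
                    k: int = 3) -> tuple:
    """Fast-path (accuracy, margin) used by the evolutionary selector.

    Same rule as :func:`fit` + :func:`predict` (z-scoring learned on the
    training split, constant features dropped, stable tie-break, majority
    vote), without object construction overhead.  The margin is the mean of
    ``sign(correct) * |P(+) - 0.5| * 2`` over test cases — in [-1, 1], it
    measures how decisively the neighbour votes agree with the true class
    and is used only to rank chromosomes of equal accuracy.
    """
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all selected features are constant in training")
    Xtr = (X_train[:, keep] - mu[keep]) / sd[keep]
    Xte = (X_test[:, keep] - mu[keep]) / sd[keep]
    d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=-1)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = y_train[nbr].sum(axis=1)
    pred = votes * 2 > k
    correct = pred == y_test
    frac = votes / float(k)
    margin = (np.where(correct, 1.0, -1.0) * np.abs(frac - 0.5) * 2.0).mean()
    return float(correct.mean()), float(margin)


def knn_accuracy(X_train: np.ndarray, y_train: np.ndarray,
                 X_test: np.ndarray, y_test: np.ndarray, k: int = 3) -> float:
    """Train/test accuracy under the fitted-z-score majority-vote rule."""
    return knn_vote_scores(X_train, y_train, X_test, y_test, k)[0]
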