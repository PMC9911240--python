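"""Brute-force K-nearest-neighbor models (classification and regression).

Neighbors are found by exhaustive Euclidean distance; ranking ties resolve
by the lower training index (stable sort), so predictions are deterministic.
Classification uses an unweighted majority vote with voting ties broken by
the class of the single nearest neighbor; regression uses an
inverse-distance-weighted mean of the neighbor responses, with exact matches
(distance zero) returning the mean response of the matching points.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["KNNClassifier", "KNNRegressor"]


class _KNNBase(BaseEstimator):
    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        if not (1 <= self.k <= X.shape[0]):
            raise ValueError(f"k={self.k} must satisfy 1 <= k <= n_train={X.shape[0]}")
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def _neighbors(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices and distances of the k nearest stored points per query."""
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: model has {self.n_features_in_} features, "
                f"input has {X.shape[1]}"
            )
        dist = cdist(X, self.X_)
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.k]
        return order, np.take_along_axis(dist, order, axis=1)


class KNNClassifier(_KNNBase, ClassifierMixin):
    """Majority-vote K-nearest-neighbor classifier."""

    def fit(self, X, y):
        super().fit(X, y)
        self.classes_ = np.unique(self.y_)
        return self

    def predict(self, X):
        idx, _ = self._neighbors(X)
        out = np.empty(idx.shape[0], dtype=self.y_.dtype)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for q in range(idx.shape[0]):
            votes = np.zeros(len(self.classes_), dtype=int)
            for i in idx[q]:
                votes[class_index[self.y_[i]]] += 1
            winners = np.flatnonzero(votes == votes.max())
            if len(winners) == 1:
                out[q] = self.classes_[winners[0]]
            else:
                # voting tie: the single nearest neighbor decides
                out[q] = self.y_[idx[q, 0]]
        return out

    def to_text(self) -> str:
        check_is_fitted(self, "X_")
        lines = [f"model = knn_classifier", f"k = {self.k}"]
        lines.append("y = " + ",".join(str(v) for v in self.y_))
        for j in range(self.n_features_in_):
            lines.append(f"x_{j} = " + ",".join(repr(float(v)) for v in self.X_[:, j]))
        return "\n".join(lines) + "\n"


class KNNRegressor(_KNNBase, RegressorMixin):
    """Inverse-distance-weighted K-nearest-neighbor regressor."""

    def predict(self, X):
        idx, dist = self._neighbors(X)
        y = np.asarray(self.y_, dtype=float)
        out = np.empty(idx.shape[0])
        for q in range(idx.shape[0]):
            d = dist[q]
            exact = d == 0.0
            if exact.any():
                out[q] = float(y[idx[q][exact]].mean())
            else:
                w = 1.0 / d
                out[q] = float(np.sum(w * y[idx[q]]) / np.sum(w))
        return out

    def to_text(self) -> str:
        check_is_fitted(self, "X_")
        lines = [f"model = knn_regressor", f"k = {self.k}"]
        lines.append("y = " + ",".join(repr(float(v)) for v in self.y_))
        for j in range(self.n_features_in_):
            lines.append(f"x_{j} = " + ",".join(repr(float(v)) for v in self.X_[:, j]))
        return "\n".join(lines) + "\n"
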