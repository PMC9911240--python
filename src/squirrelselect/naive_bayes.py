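"""Gaussian naive Bayes classifier, written out from first principles.

The model assumes features are conditionally independent given the class and
normally distributed within each class; the posterior is the class prior
times the product of per-feature Gaussian densities, evaluated in log space
for numerical stability.  The class is a scikit-learn-compatible estimator
so it composes with pipelines and model selection, but the fit and the
posterior computation are authored here (library implementations serve only
as cross-checks in the test suite).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["GaussianNaiveBayes"]


class GaussianNaiveBayes(BaseEstimator, ClassifierMixin):
    """Gaussian naive Bayes with a variance smoothing floor.

    Parameters
    ----------
    var_smoothing : float, default 1e-9
        Per-class per-feature variances are floored at
        ``var_smoothing * max_feature_variance`` (the largest pooled feature
        variance in the training data), keeping likelihoods finite for
        constant features.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    class_prior_ : ndarray
        Class frequencies in the training data; sums to 1.
    theta_ : ndarray of shape (n_classes, n_features)
        Per-class feature means.
    var_ : ndarray of shape (n_classes, n_features)
        Per-class feature variances after flooring.
    """

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class; need at least two")
        self.class_prior_ = counts / counts.sum()
        max_var = float(np.var(X, axis=0).max())
        self._var_floor_ = self.var_smoothing * (max_var if max_var > 0 else 1.0)
        self.theta_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        var = np.vstack([X[y == c].var(axis=0) for c in self.classes_])  # ddof=0
        self.var_ = np.maximum(var, self._var_floor_)
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        # log P(c) + sum_j log N(x_j; mu_cj, var_cj), shape (n, n_classes)
        jll = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            mu, var = self.theta_[k], self.var_[k]
            log_density = -0.5 * (np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var)
            jll[:, k] = np.log(self.class_prior_[k]) + log_density.sum(axis=1)
        return jll

    def predict_log_proba(self, X):
        check_is_fitted(self, "theta_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: model has {self.n_features_in_} features, "
                f"input has {X.shape[1]}"
            )
        jll = self._joint_log_likelihood(X)
        return jll - logsumexp(jll, axis=1, keepdims=True)

    def predict_proba(self, X):
        return np.exp(self.predict_log_proba(X))

    def predict(self, X):
        # argmax posterior; ties resolve to the lower class label
        return self.classes_[np.argmax(self.predict_log_proba(X), axis=1)]

    # -- flat key-value serialization ------------------------------------

    def to_text(self) -> str:
        """Serialize the fitted model to a flat ``key = values`` text block."""
        check_is_fitted(self, "theta_")
        lines = [
            f"model = gaussian_naive_bayes",
            f"var_smoothing = {self.var_smoothing!r}",
            "classes = " + ",".join(str(c) for c in self.classes_),
            "class_prior = " + ",".join(repr(float(p)) for p in self.class_prior_),
        ]
        for k, c in enumerate(self.classes_):
            lines.append(f"theta_{c} = " + ",".join(repr(float(v)) for v in self.theta_[k]))
            lines.append(f"var_{c} = " + ",".join(repr(float(v)) for v in self.var_[k]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GaussianNaiveBayes":
        fields = {}
        for line in text.strip().splitlines():
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
        if fields.get("model") != "gaussian_naive_bayes":
            raise ValueError("text does not describe a gaussian_naive_bayes model")
        model = cls(var_smoothing=float(fields["var_smoothing"]))
        classes = fields["classes"].split(",")
        try:
            model.classes_ = np.array([int(c) for c in classes])
        except ValueError:
            model.classes_ = np.array(classes)
        model.class_prior_ = np.array([float(v) for v in fields["class_prior"].split(",")])
        model.theta_ = np.vstack(
            [[float(v) for v in fields[f"theta_{c}"].split(",")] for c in classes]
        )
        model.var_ = np.vstack(
            [[float(v) for v in fields[f"var_{c}"].split(",")] for c in classes]
        )
        model.n_features_in_ = model.theta_.shape[1]
        return model
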