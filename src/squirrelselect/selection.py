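"""Wrapper feature selection driven by the squirrel search optimizer.

The optimizer searches the continuous unit box ``[0, 1]^D`` (one coordinate
per feature); a position is binarized into a feature mask by a fixed
threshold, and the mask is scored by cross-validated performance of a
predictive model trained on the masked columns, plus a small sparsity
penalty.  Lower fitness is better:

``fitness = (1 - w) * error_term + w * |selected| / D``

where the error term is ``1 - mean CV accuracy`` for classification or the
IQR-normalized mean CV absolute error for survival-time regression, and
``w`` is the sparsity weight (default 0.01, so predictive performance
dominates).

:class:`SquirrelSearchSelector` packages the loop as a scikit-learn
transformer (``fit`` / ``transform`` / ``get_support``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import iqr
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .config import SSAConfig
from .data import FeatureTable
from .naive_bayes import GaussianNaiveBayes
from .neighbors import KNNClassifier, KNNRegressor
from .ssa import run_ssa

__all__ = [
    "FeatureMask",
    "WrapperConfig",
    "binarize_position",
    "fitness_classification",
    "fitness_regression",
    "select_features",
    "SquirrelSearchSelector",
]

TASKS = ("classify_5yr", "regress_months")
MODELS = ("naive_bayes", "knn")


@dataclass
class FeatureMask:
    """Boolean feature subset together with the position it came from."""

    selected: np.ndarray
    source_position: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        self.source_position = np.asarray(self.source_position, dtype=float)
        if self.selected.shape != self.source_position.shape:
            raise ValueError("mask and source position have different lengths")
        if not self.selected.any():
            raise ValueError("a feature mask must select at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


@dataclass
class WrapperConfig:
    """Settings of the wrapper loop (task, model, CV, sparsity pressure)."""

    task: str = "classify_5yr"
    model: str = "naive_bayes"
    cv_folds: int = 5
    sparsity_weight: float = 0.01
    knn_k: int = 5
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 <= self.sparsity_weight < 1.0):
            raise ValueError("sparsity_weight must lie in [0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def binarize_position(
    position: np.ndarray,
    lower: np.ndarray | float = 0.0,
    upper: np.ndarray | float = 1.0,
    threshold: float = 0.5,
) -> FeatureMask:
    """Threshold a continuous position into a non-empty feature mask.

    Feature ``j`` is selected iff its bound-normalized coordinate exceeds
    ``threshold``.  If nothing passes, the single feature with the largest
    normalized coordinate is selected (ties to the lowest index), so the
    mask is never empty.
    """
    position = np.asarray(position, dtype=float)
    lo = np.broadcast_to(np.asarray(lower, dtype=float), position.shape)
    hi = np.broadcast_to(np.asarray(upper, dtype=float), position.shape)
    width = hi - lo
    if np.any(width <= 0):
        raise ValueError("degenerate bounds: upper must exceed lower for every feature")
    normalized = (position - lo) / width
    selected = normalized > threshold
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(normalized))] = True
    return FeatureMask(selected=selected, source_position=position)


def _classifier(wcfg: WrapperConfig):
    if wcfg.model == "naive_bayes":
        return GaussianNaiveBayes()
    return KNNClassifier(k=wcfg.knn_k)


def _fold_iterator(y, n_samples, wcfg, seed, stratified):
    if stratified:
        splitter = StratifiedKFold(n_splits=wcfg.cv_folds, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros((n_samples, 1)), y))
    splitter = KFold(n_splits=wcfg.cv_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros((n_samples, 1))))


def _stratified_folds_with_retry(y, wcfg, rng):
    """Stratified CV folds whose training halves all contain both classes.

    If a draw produces a single-class training fold the folds are redrawn
    once with a fresh seed; a second failure is an error (the class balance
    is too extreme for the requested fold count).
    """
    for attempt in range(2):
        seed = int(rng.integers(0, 2**31))
        try:
            folds = _fold_iterator(y, len(y), wcfg, seed, stratified=True)
        except ValueError as err:
            raise ValueError(f"cannot stratify {wcfg.cv_folds} folds: {err}") from err
        if all(len(np.unique(y[tr])) >= 2 for tr, _ in folds):
            return folds
    raise ValueError(
        f"stratified {wcfg.cv_folds}-fold CV produced a single-class training fold twice"
    )


def fitness_classification(
    mask: FeatureMask,
    X: np.ndarray,
    y: np.ndarray,
    wcfg: WrapperConfig,
    rng: np.random.Generator,
) -> float:
    """Wrapper fitness of a mask for the five-year-survival task (lower is better)."""
    cols = X[:, mask.selected]
    folds = _stratified_folds_with_retry(y, wcfg, rng)
    accuracies = []
    for train, test in folds:
        model = _classifier(wcfg).fit(cols[train], y[train])
        accuracies.append(float(np.mean(model.predict(cols[test]) == y[test])))
    frac = mask.n_selected / X.shape[1]
    w = wcfg.sparsity_weight
    return (1.0 - w) * (1.0 - float(np.mean(accuracies))) + w * frac


def fitness_regression(
    mask: FeatureMask,
    X: np.ndarray,
    months: np.ndarray,
    wcfg: WrapperConfig,
    rng: np.random.Generator,
) -> float:
    """Wrapper fitness of a mask for survival-time regression (lower is better).

    The per-fold mean absolute error is normalized by the interquartile
    range of the response so the error term is scale-free and commensurate
    with the sparsity term.
    """
    months = np.asarray(months, dtype=float)
    spread = float(iqr(months))
    if spread == 0.0:
        raise ValueError("survival-months response is constant (zero IQR)")
    cols = X[:, mask.selected]
    seed = int(rng.integers(0, 2**31))
    folds = _fold_iterator(None, len(months), wcfg, seed, stratified=False)
    errors = []
    for train, test in folds:
        k = min(wcfg.knn_k, len(train))
        model = KNNRegressor(k=k).fit(cols[train], months[train])
        errors.append(float(np.mean(np.abs(model.predict(cols[test]) - months[test]))))
    frac = mask.n_selected / X.shape[1]
    w = wcfg.sparsity_weight
    return (1.0 - w) * (float(np.mean(errors)) / spread) + w * frac


class SquirrelSearchSelector(SelectorMixin, BaseEstimator):
    """Feature selection by squirrel search over binarized positions.

    A scikit-learn transformer: ``fit(X, y)`` runs the squirrel search
    wrapper on the supplied data (``y`` is the binary survival label for the
    classification task, the survival months for the regression task),
    after which ``get_support()`` / ``transform`` expose the selected
    columns.

    Parameters
    ----------
    task : {"classify_5yr", "regress_months"}
        Which prediction task scores candidate subsets.
    model : {"naive_bayes", "knn"}
        Classifier inside the wrapper (regression always uses KNN).
    cv_folds, sparsity_weight, knn_k, threshold
        Wrapper settings; see :class:`WrapperConfig`.
    n_squirrels, n_acorn, max_iterations, predator_prob, seed
        Squirrel search settings; see :class:`~squirrelselect.config.SSAConfig`.
        The search box is always ``[0, 1]^D``.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Selected-feature mask of the best position ever visited.
    best_position_ : ndarray
        The continuous position behind ``support_``.
    best_fitness_ : float
        Its wrapper fitness.
    trace_ : pandas.DataFrame
        Per-iteration best/mean fitness and winter flags.
    """

    def __init__(
        self,
        task: str = "classify_5yr",
        model: str = "naive_bayes",
        cv_folds: int = 5,
        sparsity_weight: float = 0.01,
        knn_k: int = 5,
        threshold: float = 0.5,
        n_squirrels: int = 30,
        n_acorn: int = 3,
        max_iterations: int = 60,
        predator_prob: float = 0.1,
        seed: int = 0,
    ):
        self.task = task
        self.model = model
        self.cv_folds = cv_folds
        self.sparsity_weight = sparsity_weight
        self.knn_k = knn_k
        self.threshold = threshold
        self.n_squirrels = n_squirrels
        self.n_acorn = n_acorn
        self.max_iterations = max_iterations
        self.predator_prob = predator_prob
        self.seed = seed

    def _wrapper_config(self) -> WrapperConfig:
        return WrapperConfig(
            task=self.task,
            model=self.model,
            cv_folds=self.cv_folds,
            sparsity_weight=self.sparsity_weight,
            knn_k=self.knn_k,
            threshold=self.threshold,
        )

    def _ssa_config(self) -> SSAConfig:
        return SSAConfig(
            n_squirrels=self.n_squirrels,
            n_acorn=self.n_acorn,
            max_iterations=self.max_iterations,
            predator_prob=self.predator_prob,
            lower_bound=0.0,
            upper_bound=1.0,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        wcfg = self._wrapper_config()
        scfg = self._ssa_config()
        d = X.shape[1]
        rng = np.random.default_rng(scfg.seed)
        # One fold-assignment seed per run: the fitness is then a
        # deterministic function of the mask, so elitism is meaningful at
        # the mask level.
        fold_rng = np.random.default_rng(int(rng.integers(0, 2**31)))

        if wcfg.task == "classify_5yr":
            y = y.astype(int)

            def score(mask: FeatureMask) -> float:
                return fitness_classification(mask, X, y, wcfg, _ReplayRNG(fold_rng))
        else:
            months = y.astype(float)

            def score(mask: FeatureMask) -> float:
                return fitness_regression(mask, X, months, wcfg, _ReplayRNG(fold_rng))

        cache: dict[bytes, float] = {}

        def fitness(position: np.ndarray) -> float:
            mask = binarize_position(position, 0.0, 1.0, wcfg.threshold)
            key = np.packbits(mask.selected).tobytes()
            if key not in cache:
                cache[key] = score(mask)
            return cache[key]

        population, trace = run_ssa(scfg, fitness, d, rng)
        mask = binarize_position(population.best_position, 0.0, 1.0, wcfg.threshold)
        self.support_ = mask.selected
        self.best_position_ = population.best_position
        self.best_fitness_ = float(population.best_fitness)
        self.trace_ = trace
        self.n_features_in_ = d
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def selection_report(self, feature_names=None) -> pd.DataFrame:
        """Per-feature report: selected flag, normalized position, rank."""
        check_is_fitted(self, "support_")
        if feature_names is None:
            feature_names = [f"feature_{j}" for j in range(self.n_features_in_)]
        position = np.asarray(self.best_position_, dtype=float)
        rank = np.empty(len(position), dtype=int)
        rank[np.argsort(-position, kind="stable")] = np.arange(1, len(position) + 1)
        return pd.DataFrame(
            {
                "feature": list(feature_names),
                "selected": self.support_,
                "normalized_position": position,
                "rank": rank,
            }
        )


class _ReplayRNG:
    """Re-deal the same fold seeds at every fitness evaluation.

    The fold-assignment stream is fixed once per selection run; each
    evaluation replays it from the start, so identical masks always see
    identical folds.
    """

    def __init__(self, source: np.random.Generator):
        self._state = source.bit_generator.state

    def integers(self, low, high=None):
        g = np.random.Generator(np.random.PCG64())
        g.bit_generator.state = self._state
        value = g.integers(low, high)
        self._state = g.bit_generator.state
        return value


def select_features(
    table: FeatureTable,
    scfg: SSAConfig | None = None,
    wcfg: WrapperConfig | None = None,
) -> tuple[FeatureMask, pd.DataFrame]:
    """Functional front end: run the wrapper on a table, return mask + trace."""
    wcfg = wcfg or WrapperConfig()
    scfg = scfg or SSAConfig(n_squirrels=30, max_iterations=60, lower_bound=0.0, upper_bound=1.0)
    if wcfg.task == "classify_5yr":
        if table.y is None:
            raise ValueError("classification task needs a binary label column")
        target = table.y
    else:
        if table.months is None:
            raise ValueError("regression task needs a survival-months column")
        target = table.months
    selector = SquirrelSearchSelector(
        task=wcfg.task,
        model=wcfg.model,
        cv_folds=wcfg.cv_folds,
        sparsity_weight=wcfg.sparsity_weight,
        knn_k=wcfg.knn_k,
        threshold=wcfg.threshold,
        n_squirrels=scfg.n_squirrels,
        n_acorn=scfg.n_acorn,
        max_iterations=scfg.max_iterations,
        predator_prob=scfg.predator_prob,
        seed=scfg.seed,
    )
    selector.fit(table.X, target)
    mask = FeatureMask(selected=selector.support_, source_position=selector.best_position_)
    return mask, selector.trace_
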