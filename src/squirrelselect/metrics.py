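"""Split protocol, confusion-based metrics, MAE and repeated evaluation.

The experiment protocol splits a cohort 7:1:2 into train / validation /
test, runs the squirrel-search wrapper on the training split, uses the
validation split only to pick the model hyperparameter (``k`` for KNN,
variance smoothing for naive Bayes), and touches the test split exactly
once per repeat.  Repeats (default 5) re-draw the split with fresh seeds
and are aggregated by the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .config import SSAConfig
from .data import FeatureTable
from .naive_bayes import GaussianNaiveBayes
from .neighbors import KNNClassifier, KNNRegressor
from .selection import SquirrelSearchSelector, WrapperConfig

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "EvalReport",
    "split_data",
    "confusion",
    "metrics_from_confusion",
    "mae",
    "run_experiment",
]

KNN_K_GRID = (1, 3, 5, 7)
NB_SMOOTHING_GRID = (1e-9, 1e-6, 1e-3)


@dataclass
class SplitSpec:
    """Train/validation/test split protocol (default 7:1:2, five repeats)."""

    train_frac: float = 0.7
    valid_frac: float = 0.1
    test_frac: float = 0.2
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.valid_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train_frac, self.valid_frac, self.test_frac) <= 0:
            raise ValueError("all split fractions must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ConfusionCounts:
    """Binary confusion counts; the positive class is 'survives >= 5 years'."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    """Aggregated evaluation of one experiment.

    ``precision`` is ``None`` (flagged, not NaN-propagated) when no repeat
    produced a positive prediction.  ``per_repeat`` holds the raw per-repeat
    records and ``traces`` the wrapper convergence trace of each repeat.
    """

    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    tpr: float | None = None
    error_rate: float | None = None
    mae_months: float | None = None
    per_repeat: list[dict] = field(default_factory=list)
    traces: list[pd.DataFrame] = field(default_factory=list)
    precision_undefined: bool = False

    def per_repeat_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_repeat)


def split_data(
    table: FeatureTable,
    spec: SplitSpec,
    seed: int | None = None,
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Random (optionally stratified) 7:1:2 partition of a table.

    Deterministic under ``seed`` (defaults to ``spec.seed``).  Errors if a
    class is absent from any split.
    """
    if seed is None:
        seed = spec.seed
    n = table.n_samples
    index = np.arange(n)
    strat = table.y if (spec.stratified and table.y is not None) else None
    # integer split sizes keep the 7:1:2 proportion exact (e.g. 70/10/20 at n=100)
    n_test = int(round(n * spec.test_frac))
    n_valid = int(round(n * spec.valid_frac))
    rest, test = train_test_split(index, test_size=n_test, random_state=seed, stratify=strat)
    strat_rest = table.y[rest] if strat is not None else None
    train, valid = train_test_split(
        rest, test_size=n_valid, random_state=seed + 1, stratify=strat_rest
    )
    parts = (table.subset_rows(np.sort(train)),
             table.subset_rows(np.sort(valid)),
             table.subset_rows(np.sort(test)))
    if table.y is not None:
        for name, part in zip(("train", "validation", "test"), parts):
            if len(np.unique(part.y)) < 2:
                raise ValueError(f"class absent from the {name} split; need more data")
    return parts


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts of binary predictions (1 = survives five years)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def metrics_from_confusion(cc: ConfusionCounts) -> dict:
    """Accuracy, precision, recall (= TPR) and error rate from counts.

    Precision is ``None`` with ``precision_undefined=True`` when no positive
    prediction was made (tp + fp = 0).
    """
    n = cc.n
    if n == 0:
        raise ValueError("empty confusion counts")
    accuracy = (cc.tp + cc.tn) / n
    recall = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) > 0 else None
    if cc.tp + cc.fp > 0:
        precision, undefined = cc.tp / (cc.tp + cc.fp), False
    else:
        precision, undefined = None, True
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "tpr": recall,
        "error_rate": 1.0 - accuracy,
        "precision_undefined": undefined,
    }


def mae(y_true_months, y_pred_months) -> float:
    """Mean absolute error in months."""
    y_true = np.asarray(y_true_months, dtype=float)
    y_pred = np.asarray(y_pred_months, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    return float(np.mean(np.abs(y_true - y_pred)))


def _pick_classifier(X_tr, y_tr, X_va, y_va, wcfg: WrapperConfig):
    """Model choice on the validation split: knn_k or NB smoothing grid."""
    best = None
    if wcfg.model == "knn":
        for k in KNN_K_GRID:
            if k > len(y_tr):
                continue
            model = KNNClassifier(k=k).fit(X_tr, y_tr)
            acc = float(np.mean(model.predict(X_va) == y_va))
            if best is None or acc > best[0]:
                best = (acc, model, {"knn_k": k})
    else:
        for vs in NB_SMOOTHING_GRID:
            model = GaussianNaiveBayes(var_smoothing=vs).fit(X_tr, y_tr)
            acc = float(np.mean(model.predict(X_va) == y_va))
            if best is None or acc > best[0]:
                best = (acc, model, {"var_smoothing": vs})
    return best[1], best[2]


def _pick_regressor(X_tr, y_tr, X_va, y_va):
    best = None
    for k in KNN_K_GRID:
        if k > len(y_tr):
            continue
        model = KNNRegressor(k=k).fit(X_tr, y_tr)
        err = mae(y_va, model.predict(X_va))
        if best is None or err < best[0]:
            best = (err, model, {"knn_k": k})
    return best[1], best[2]


def run_experiment(
    table: FeatureTable,
    scfg: SSAConfig | None = None,
    wcfg: WrapperConfig | None = None,
    spec: SplitSpec | None = None,
) -> EvalReport:
    """Repeated split -> select -> tune -> test evaluation of the pipeline.

    Each repeat draws a fresh 7:1:2 split, runs the squirrel-search wrapper
    on the training split only, picks the model hyperparameter on the
    validation split, refits on the training split and scores the test
    split once.  Metrics are averaged over repeats (precision excludes
    repeats where it was undefined, with a warning).
    """
    wcfg = wcfg or WrapperConfig()
    spec = spec or SplitSpec()
    scfg = scfg or SSAConfig(
        n_squirrels=30, max_iterations=60, lower_bound=0.0, upper_bound=1.0
    )
    report = EvalReport()
    for r in range(spec.n_repeats):
        repeat_seed = int((spec.seed + 7919 * r) % (2**31 - 1))
        try:
            train, valid, test = split_data(table, spec, seed=repeat_seed)
            record = _single_cycle(train, valid, test, scfg, wcfg, repeat_seed)
        except Exception as err:
            raise RuntimeError(f"repeat {r}: {err}") from err
        record["repeat"] = r
        report.per_repeat.append(record)
        report.traces.append(record.pop("trace"))

    if wcfg.task == "classify_5yr":
        for key in ("accuracy", "recall", "tpr", "error_rate"):
            setattr(report, key, float(np.mean([rec[key] for rec in report.per_repeat])))
        defined = [rec["precision"] for rec in report.per_repeat if rec["precision"] is not None]
        if len(defined) < len(report.per_repeat):
            warnings.warn(
                "precision undefined (no positive predictions) in "
                f"{len(report.per_repeat) - len(defined)} repeat(s); excluded from the mean"
            )
            report.precision_undefined = len(defined) == 0
        report.precision = float(np.mean(defined)) if defined else None
    else:
        report.mae_months = float(np.mean([rec["mae_months"] for rec in report.per_repeat]))
    return report


def _single_cycle(train, valid, test, scfg: SSAConfig, wcfg: WrapperConfig, seed: int) -> dict:
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
        seed=seed,
    )
    if wcfg.task == "classify_5yr":
        target_tr, target_va, target_te = train.y, valid.y, test.y
    else:
        target_tr, target_va, target_te = train.months, valid.months, test.months
    selector.fit(train.X, target_tr)
    cols = selector.support_
    X_tr, X_va, X_te = train.X[:, cols], valid.X[:, cols], test.X[:, cols]

    record: dict = {
        "n_selected": int(cols.sum()),
        "selected_indices": np.flatnonzero(cols).tolist(),
        "wrapper_fitness": selector.best_fitness_,
        "trace": selector.trace_,
    }
    if wcfg.task == "classify_5yr":
        model, chosen = _pick_classifier(X_tr, target_tr, X_va, target_va, wcfg)
        y_pred = model.predict(X_te)
        record.update(metrics_from_confusion(confusion(target_te, y_pred)))
    else:
        model, chosen = _pick_regressor(X_tr, target_tr, X_va, target_va)
        record["mae_months"] = mae(target_te, model.predict(X_te))
    record.update(chosen)
    return record
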