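"""Feature-table container and CSV ingestion.

A :class:`FeatureTable` is the package's in-memory unit of clinical data:
a named numeric matrix (rows = patients, columns = features), an optional
binary five-year-survival label, and an optional continuous survival-time
column in months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_table"]

logger = logging.getLogger("squirrelselect")


@dataclass
class FeatureTable:
    """Validated numeric feature matrix with optional outcome columns.

    ``y`` holds the binary label (1 = survives five years or longer),
    ``months`` the observed survival time in months.  ``provenance`` records
    where the table came from (source path, generator seed) for run
    manifests.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray | None = None
    months: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match the matrix width")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one feature column")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing or non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("label vector length does not match the matrix")
            if not set(np.unique(self.y)) <= {0, 1}:
                raise ValueError("labels must be binary (0/1)")
        if self.months is not None:
            self.months = np.asarray(self.months, dtype=float)
            if self.months.shape[0] != self.X.shape[0]:
                raise ValueError("months vector length does not match the matrix")
            if np.any(self.months < 0) or not np.all(np.isfinite(self.months)):
                raise ValueError("months must be finite and non-negative")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, index: Sequence[int]) -> "FeatureTable":
        index = np.asarray(index, dtype=int)
        return FeatureTable(
            feature_names=list(self.feature_names),
            X=self.X[index],
            y=None if self.y is None else self.y[index],
            months=None if self.months is None else self.months[index],
            provenance=dict(self.provenance),
        )

    def to_frame(self, label_col: str = "survived_5yr", months_col: str = "survival_months") -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        if self.y is not None:
            frame[label_col] = self.y
        if self.months is not None:
            frame[months_col] = self.months
        return frame

    def write_csv(self, path, label_col: str = "survived_5yr", months_col: str = "survival_months") -> None:
        self.to_frame(label_col, months_col).to_csv(path, index=False)


def read_table(
    path,
    label_col: str | None = None,
    months_col: str | None = None,
) -> FeatureTable:
    """Read and validate a feature table from a headered CSV file.

    Feature columns are coerced to numeric; rows with any missing value are
    dropped with a logged count.  The label column, if named, is mapped onto
    {0, 1} (two distinct values, mapped in sorted order) and the mapping is
    logged; more than two distinct label values is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: table is empty")

    outcome_cols = [c for c in (label_col, months_col) if c is not None]
    for col in outcome_cols:
        if col not in frame.columns:
            raise ValueError(
                f"{path}: required column {col!r} not found; available: {list(frame.columns)}"
            )
    feature_cols = [c for c in frame.columns if c not in outcome_cols]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns left after outcome columns")

    for col in feature_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().sum() > frame[col].isna().sum():
            raise ValueError(f"{path}: feature column {col!r} contains non-numeric values")
        frame[col] = coerced
    if months_col is not None:
        frame[months_col] = pd.to_numeric(frame[months_col], errors="raise")

    before = len(frame)
    frame = frame.dropna(subset=feature_cols + [c for c in outcome_cols])
    dropped = before - len(frame)
    if dropped:
        logger.info("dropped %d row(s) with missing values while reading %s", dropped, path)
    if len(frame) == 0:
        raise ValueError(f"{path}: no rows left after dropping missing values")

    y = None
    if label_col is not None:
        raw = frame[label_col]
        values = sorted(pd.unique(raw))
        if len(values) > 2:
            raise ValueError(
                f"{path}: label column {label_col!r} has {len(values)} distinct values "
                f"{values}; a binary label is required"
            )
        mapping = {v: i for i, v in enumerate(values)}
        logger.info("label mapping for %s: %s", label_col, mapping)
        y = raw.map(mapping).to_numpy(dtype=int)

    months = None
    if months_col is not None:
        months = frame[months_col].to_numpy(dtype=float)

    return FeatureTable(
        feature_names=feature_cols,
        X=frame[feature_cols].to_numpy(dtype=float),
        y=y,
        months=months,
        provenance={"source": str(path), "dropped_rows": dropped},
    )
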