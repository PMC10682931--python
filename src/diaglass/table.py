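"""Tabular patient cohorts: the unit every pipeline stage consumes.

A :class:`FeatureTable` is a thin, validated wrapper around a feature
matrix ``X``, a binary outcome ``y`` and a per-feature kind schema
(``continuous`` or ``binary``).  Binary features are coded 0/1 and pass
through scaling untouched; continuous features are z-scored before any
distance-based step (SMOTE, Tomek links, LIME perturbation) so that
Euclidean neighborhoods are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"
_KINDS = (CONTINUOUS, BINARY)


@dataclass
class FeatureTable:
    """Rows x named features plus a binary outcome.

    Parameters
    ----------
    feature_names : list of str
        Column names, in the order of the columns of ``X``.
    X : ndarray of shape (n, d)
        Feature matrix; binary features coded 0/1.
    y : ndarray of shape (n,)
        Outcome labels, values in {0, 1}.
    schema : list of str
        Per-feature kind, each ``"continuous"`` or ``"binary"``.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    schema: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = self.X.shape
        if len(self.feature_names) != d:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if len(set(self.feature_names)) != d:
            raise ValueError("duplicate feature names")
        if self.y.shape != (n,):
            raise ValueError("y length must match number of rows")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y values must be 0 or 1")
        if np.isnan(self.X).any():
            raise ValueError("X contains NaN; impute or drop before building")
        if not self.schema:
            self.schema = infer_schema(self.X)
        if len(self.schema) != d:
            raise ValueError("schema length must match number of columns")
        for kind in self.schema:
            if kind not in _KINDS:
                raise ValueError(f"unknown feature kind {kind!r}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(count of y==0, count of y==1)."""
        return int((self.y == 0).sum()), int((self.y == 1).sum())

    def continuous_mask(self) -> np.ndarray:
        return np.array([k == CONTINUOUS for k in self.schema])

    def copy(self) -> "FeatureTable":
        return replace(
            self,
            feature_names=list(self.feature_names),
            X=self.X.copy(),
            y=self.y.copy(),
            schema=list(self.schema),
        )

    def subset(self, idx) -> "FeatureTable":
        return replace(
            self,
            feature_names=list(self.feature_names),
            X=self.X[idx],
            y=self.y[idx],
            schema=list(self.schema),
        )

    def to_dataframe(self, label: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label] = self.y
        return df


def infer_schema(X: np.ndarray) -> list[str]:
    """Column kind inference: at most two distinct values -> binary."""
    schema = []
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        if len(vals) <= 2 and np.isin(vals, (0.0, 1.0)).all():
            schema.append(BINARY)
        else:
            schema.append(CONTINUOUS)
    return schema


def from_dataframe(
    df: pd.DataFrame, label: str = "class", schema: list[str] | None = None
) -> FeatureTable:
    """Build a FeatureTable from a DataFrame with a label column."""
    if label not in df.columns:
        raise ValueError(f"label column {label!r} not in dataframe")
    y = df[label].to_numpy()
    X = df.drop(columns=[label]).to_numpy(dtype=float)
    names = [c for c in df.columns if c != label]
    return FeatureTable(names, X, y, schema or [])


def read_csv(
    path, label: str = "class", schema: list[str] | None = None
) -> FeatureTable:
    """Read a cohort from a comma-separated file with a header row."""
    return from_dataframe(pd.read_csv(path), label=label, schema=schema)


def write_csv(table: FeatureTable, path, label: str = "class") -> None:
    table.to_dataframe(label=label).to_csv(path, index=False)
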