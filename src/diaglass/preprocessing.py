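"""Normalization and class rebalancing: z-score, SMOTE, Tomek-link cleaning.

The pipeline order is fixed — scale, then oversample, then clean — because
both SMOTE and Tomek links reason about Euclidean neighborhoods, which are
only meaningful after continuous features are brought to a common scale.
Binary features pass through scaling unchanged and participate in distances
as 0/1 coordinates.

Scaling uses the population (divide-by-n) standard deviation so that
fit-then-apply on the same rows yields mean 0, population sd 1 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .table import FeatureTable


class PreprocessingError(Exception):
    pass


@dataclass
class ScalerParams:
    """Per-feature location/scale learned on the training split only."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if (self.sd < 0).any():
            raise ValueError("standard deviations must be nonnegative")


def zscore_fit(table: FeatureTable) -> ScalerParams:
    """Learn per-feature mean and population sd; binary columns get (0, 1)."""
    mean = table.X.mean(axis=0)
    sd = table.X.std(axis=0)  # population: divide by n
    cont = table.continuous_mask()
    mean[~cont] = 0.0
    sd[~cont] = 1.0
    return ScalerParams(mean=mean, sd=sd)


def zscore_apply(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    """(x - mean)/sd on continuous columns; sd=0 columns map to 0."""
    out = table.copy()
    sd = np.where(params.sd == 0.0, 1.0, params.sd)
    Z = (out.X - params.mean) / sd
    Z[:, params.sd == 0.0] = 0.0
    out.X = Z
    return out


def smote(
    table: FeatureTable, k: int = 5, target_ratio: float = 1.0, seed: int = 0
) -> FeatureTable:
    """Synthetic minority oversampling on interpolation segments.

    Each synthetic row is ``x + lam*(z - x)`` for a minority row ``x``, one
    of its ``k`` nearest minority neighbors ``z`` (Euclidean) and
    ``lam ~ Uniform[0, 1]``.  Minority rows are visited round-robin in a
    seeded shuffled order until minority/majority reaches ``target_ratio``.
    Original rows are always preserved; synthetics are appended.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n0, n1 = table.class_counts()
    if min(n0, n1) < 2:
        raise PreprocessingError("minority class needs at least 2 samples")
    minority = 0 if n0 < n1 else 1
    n_min, n_maj = min(n0, n1), max(n0, n1)
    n_new = int(round(target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return table.copy()
    if k > n_min - 1:
        warnings.warn(
            f"k={k} exceeds minority size - 1; clipped to {n_min - 1}",
            stacklevel=2,
        )
        k = n_min - 1

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(table.y == minority)
    Xm = table.X[min_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self

    order = rng.permutation(len(min_idx))
    synth = np.empty((n_new, table.d))
    for i in range(n_new):
        a = order[i % len(order)]
        b = neigh[a, rng.integers(k)]
        lam = rng.uniform()
        synth[i] = Xm[a] + lam * (Xm[b] - Xm[a])
    out = table.copy()
    out.X = np.vstack([out.X, synth])
    out.y = np.concatenate([out.y, np.full(n_new, minority, dtype=int)])
    return out


def tomek_links(table: FeatureTable) -> list[tuple[int, int]]:
    """Index pairs of opposite-label mutual 1-nearest neighbors."""
    nn = NearestNeighbors(n_neighbors=2).fit(table.X)
    nearest = nn.kneighbors(table.X, return_distance=False)[:, 1]
    pairs = []
    for a in range(table.n):
        b = nearest[a]
        if a < b and nearest[b] == a and table.y[a] != table.y[b]:
            pairs.append((a, int(b)))
    return pairs


def tomek_remove(table: FeatureTable) -> FeatureTable:
    """Drop the majority-class member of every Tomek link, in a single pass."""
    n0, n1 = table.class_counts()
    if n0 == 0 or n1 == 0:
        raise PreprocessingError("Tomek cleaning needs both classes present")
    majority = 0 if n0 > n1 else 1
    drop = set()
    for a, b in tomek_links(table):
        member = a if table.y[a] == majority else b
        if table.y[member] == majority:
            drop.add(member)
    keep = np.array([i for i in range(table.n) if i not in drop], dtype=int)
    return table.subset(keep)


def split(
    table: FeatureTable, test_fraction: float, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split, deterministic under ``seed``."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(table.n)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=table.y,
    )
    train, test = table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))
    for part, name in ((train, "train"), (test, "test")):
        if min(part.class_counts()) == 0:
            raise PreprocessingError(f"a class is absent from the {name} split")
    return train, test


def prepare_training(
    train: FeatureTable,
    rebalance: bool = True,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureTable, ScalerParams]:
    """Fixed-order training pipeline: scale -> SMOTE -> Tomek cleaning.

    Rebalancing is per-dataset configurable (``rebalance=False`` scales
    only): heavily imbalanced cohorts benefit, already-balanced ones are
    returned untouched by SMOTE anyway.
    """
    params = zscore_fit(train)
    out = zscore_apply(train, params)
    if rebalance:
        out = smote(out, k=k, target_ratio=target_ratio, seed=seed)
        out = tomek_remove(out)
    return out, params
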