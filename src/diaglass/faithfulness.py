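"""Explanation faithfulness metrics: monotonicity and implementation invariance.

Monotonicity asks whether attribution magnitudes rank features the same way
as their expected importances; it is the Spearman rank correlation between
|weights| and the expected values, so any strictly increasing transform of
either side leaves it unchanged.  Implementation invariance asks whether
functionally equivalent models — retrainings of the same architecture on the
same data under different seeds — yield the same top-k feature sets, scored
by the Jaccard similarity averaged over seed pairs and evaluation instances.

What counts as "expected importance" depends on context: on synthetic
cohorts the planted generative coefficients provide ground truth; on real
data a model-derived oracle such as drop-column importance can be supplied.
The metric takes expectations as an explicit argument either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .attribution import AttributionVector, top_k
from .table import FeatureTable


class FaithfulnessError(Exception):
    pass


def spearman_rho(a, b) -> float:
    """Spearman correlation: Pearson on average-ranked values, ties averaged."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise FaithfulnessError("Spearman undefined for a constant vector")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def monotonicity(attr: AttributionVector, expected: dict | np.ndarray) -> float:
    """Spearman rho between |attribution weights| and expected importances.

    ``expected`` is either a vector aligned with ``attr.feature_names`` or a
    feature-name -> importance mapping over the same feature set.
    """
    if isinstance(expected, dict):
        missing = set(attr.feature_names) - set(expected)
        if missing:
            raise FaithfulnessError(f"expected importances missing {missing}")
        exp = np.array([expected[f] for f in attr.feature_names], dtype=float)
    else:
        exp = np.asarray(expected, dtype=float)
    if (exp < 0).any():
        raise ValueError("expected importances must be nonnegative")
    return spearman_rho(np.abs(attr.weights), exp)


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; undefined when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise FaithfulnessError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def implementation_invariance(
    train_fn,
    attribute_fn,
    table: FeatureTable,
    instances: np.ndarray,
    n_seeds: int = 5,
    k: int = 5,
) -> float:
    """Mean top-k Jaccard of attributions across seeded retrainings.

    ``train_fn(table, seed) -> model`` and ``attribute_fn(model, x) ->
    AttributionVector``.  The model is retrained ``n_seeds`` times on
    identical data; for every instance and unordered seed pair the Jaccard
    of top-k feature sets is computed and the grand mean returned.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    models = [train_fn(table, seed) for seed in range(n_seeds)]
    scores = []
    for x in instances:
        sets = [set(top_k(attribute_fn(m, x), k)) for m in models]
        for a, b in combinations(sets, 2):
            scores.append(jaccard(a, b))
    return float(np.mean(scores))


@dataclass
class FaithfulnessReport:
    dataset: str
    model: str
    method: str
    monotonicity_rho: float
    invariance_jaccard: float
    k: int
    n_seeds: int
    n_instances: int
    expected_source: str = "planted"

    def __post_init__(self) -> None:
        if not -1.0 <= self.monotonicity_rho <= 1.0:
            raise ValueError("monotonicity must be in [-1, 1]")
        if not 0.0 <= self.invariance_jaccard <= 1.0:
            raise ValueError("invariance must be in [0, 1]")

    def to_row(self) -> dict:
        return {
            "dataset": self.dataset,
            "model": self.model,
            "method": self.method,
            "monotonicity": self.monotonicity_rho,
            "implementation_invariance": self.invariance_jaccard,
            "k": self.k,
            "n_seeds": self.n_seeds,
            "n_instances": self.n_instances,
            "expected_source": self.expected_source,
        }


def faithfulness_report(
    train_fn,
    attribute_fn,
    table: FeatureTable,
    expected: dict,
    instances: np.ndarray,
    dataset: str = "synthetic",
    model_name: str = "model",
    method: str = "lime",
    n_seeds: int = 5,
    k: int = 5,
    expected_source: str = "planted",
) -> FaithfulnessReport:
    """Bundle monotonicity (mean over instances) and implementation invariance."""
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    model = train_fn(table, 0)
    rhos = [monotonicity(attribute_fn(model, x), expected) for x in instances]
    inv = implementation_invariance(
        train_fn, attribute_fn, table, instances, n_seeds=n_seeds, k=k
    )
    return FaithfulnessReport(
        dataset=dataset,
        model=model_name,
        method=method,
        monotonicity_rho=float(np.mean(rhos)),
        invariance_jaccard=inv,
        k=k,
        n_seeds=n_seeds,
        n_instances=len(instances),
        expected_source=expected_source,
    )
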