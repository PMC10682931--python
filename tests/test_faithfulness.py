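"""Faithfulness metrics: Spearman monotonicity and top-k Jaccard invariance."""

import numpy as np
import pytest

from diaglass import FeatureTable
from diaglass.attribution import AttributionVector, LimeConfig, ShapleyConfig, lime_explain, shapley_explain
from diaglass.faithfulness import (
    FaithfulnessError,
    FaithfulnessReport,
    faithfulness_report,
    implementation_invariance,
    jaccard,
    monotonicity,
    spearman_rho,
)


def test_spearman_perfect_orders():
    assert spearman_rho([3, 2, 1], [30, 20, 10]) == pytest.approx(1.0)
    assert spearman_rho([3, 2, 1], [10, 20, 30]) == pytest.approx(-1.0)


def test_spearman_ties_average_ranks():
    """[1,2,2,4] vs [1,3,2,4]: Pearson on hand-assigned average ranks."""
    a_ranks = np.array([1.0, 2.5, 2.5, 4.0])
    b_ranks = np.array([1.0, 3.0, 2.0, 4.0])
    expected = np.corrcoef(a_ranks, b_ranks)[0, 1]
    assert spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(expected)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    a = rng.normal(size=30)
    b = rng.normal(size=30)
    base = spearman_rho(a, b)
    assert spearman_rho(np.exp(a), b) == pytest.approx(base)
    assert spearman_rho(a, b**3 + 5 * b) == pytest.approx(base)


def test_spearman_constant_vector_rejected():
    with pytest.raises(FaithfulnessError):
        spearman_rho([1, 1, 1], [1, 2, 3])


def test_monotonicity_additive_model_is_one():
    """Exact Shapley of an additive model ranks like |w_j| sd_j by closed form."""
    rng = np.random.default_rng(1)
    w = np.array([2.0, -1.2, 0.6, 0.3])
    sds = np.array([1.0, 2.0, 0.5, 1.5])
    bg = rng.normal(size=(40, 4)) * sds
    x = bg.mean(axis=0) + sds  # one sd above the background mean
    attr = shapley_explain(
        lambda X: X @ w, x, ShapleyConfig(background=bg, mode="exact"),
        feature_names=["a", "b", "c", "d"],
    )
    expected = dict(zip("abcd", np.abs(w) * sds))
    assert monotonicity(attr, expected) == pytest.approx(1.0)


def test_monotonicity_reversed_is_minus_one():
    attr = AttributionVector(["a", "b", "c"], np.array([3.0, -2.0, 1.0]), "lime")
    assert monotonicity(attr, {"a": 0.1, "b": 0.5, "c": 0.9}) == pytest.approx(-1.0)


def test_monotonicity_uses_magnitudes():
    attr = AttributionVector(["a", "b"], np.array([-3.0, 1.0]), "lime")
    assert monotonicity(attr, {"a": 2.0, "b": 1.0}) == pytest.approx(1.0)


def test_lime_monotonic_on_planted_logistic_cohort():
    """LIME on a logistic model recovers the planted importance order in
    at least 9 of 10 seeded replicates (n=2000)."""
    from sklearn.linear_model import LogisticRegression

    from diaglass import datasets
    from diaglass.preprocessing import zscore_apply, zscore_fit

    wins = 0
    for seed in range(10):
        cohort = datasets.gen_earlystage_like(
            datasets.default_earlystage_spec(n=2000, seed=seed)
        )
        expected = datasets.planted_importances(
            datasets.default_earlystage_spec(n=2000, seed=seed), cohort
        )
        scaled = zscore_apply(cohort, zscore_fit(cohort))
        lr = LogisticRegression(max_iter=1000).fit(scaled.X, scaled.y)
        predict = lambda X: lr.predict_proba(X)[:, 1]
        x = scaled.X[seed]
        attr = lime_explain(
            predict,
            x,
            scaled.schema,
            LimeConfig(n_perturbations=1500, seed=100 + seed),
            feature_names=scaled.feature_names,
        )
        if monotonicity(attr, expected) >= 0.8:
            wins += 1
    assert wins >= 9


def test_jaccard_values():
    assert jaccard({"a"}, {"a"}) == 1.0
    assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
    assert jaccard({"a"}, {"b"}) == 0.0
    with pytest.raises(FaithfulnessError):
        jaccard(set(), set())


def test_jaccard_invariant_under_renaming():
    ren = {"a": "x", "b": "y", "c": "z", "d": "w"}
    A, B = {"a", "b", "c"}, {"b", "c", "d"}
    assert jaccard({ren[e] for e in A}, {ren[e] for e in B}) == jaccard(A, B)


@pytest.fixture()
def small_table():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 4))
    y = (X[:, 0] > 0).astype(int)
    return FeatureTable(["a", "b", "c", "d"], X, y)


def test_invariance_fixed_attribution_is_one(small_table):
    train_fn = lambda table, seed: seed  # model is irrelevant
    attribute_fn = lambda model, x: AttributionVector(
        ["a", "b", "c", "d"], np.array([4.0, 3.0, 2.0, 1.0]), "lime"
    )
    got = implementation_invariance(
        train_fn, attribute_fn, small_table, small_table.X[:3], n_seeds=3, k=2
    )
    assert got == 1.0


def test_invariance_disjoint_sets_is_zero(small_table):
    def attribute_fn(model, x):
        w = [1.0, 2.0, 0.0, 0.0] if model == 0 else [0.0, 0.0, 2.0, 1.0]
        return AttributionVector(["a", "b", "c", "d"], np.array(w), "lime")

    got = implementation_invariance(
        lambda t, s: s, attribute_fn, small_table, small_table.X[:2], n_seeds=2, k=2
    )
    assert got == 0.0


def test_invariance_deterministic_pipeline_is_one():
    """A seed-independent trainer plus deterministic attribution scores 1.0."""
    from diaglass.models import train_decision_tree

    X = np.linspace(0, 1, 30).reshape(-1, 1).repeat(2, axis=1)
    y = (X[:, 0] > 0.5).astype(int)
    t = FeatureTable(["a", "b"], X, y)
    bg = t.X[:10]

    def train_fn(table, seed):
        return train_decision_tree(table, seed=0)[0]  # seed-independent

    def attribute_fn(model, x):
        return shapley_explain(
            lambda Z: model.predict_proba(Z)[:, 1],
            x,
            ShapleyConfig(background=bg, mode="exact"),
            feature_names=["a", "b"],
        )

    got = implementation_invariance(train_fn, attribute_fn, t, t.X[:3], n_seeds=3, k=1)
    assert got == 1.0


def test_report_bundles_and_serializes(small_table):
    train_fn = lambda table, seed: None
    attr = AttributionVector(["a", "b", "c", "d"], np.array([4.0, 3.0, 2.0, 1.0]), "lime")
    report = faithfulness_report(
        train_fn,
        lambda m, x: attr,
        small_table,
        {"a": 4, "b": 3, "c": 2, "d": 1},
        small_table.X[:2],
        n_seeds=2,
        k=2,
    )
    assert report.monotonicity_rho == pytest.approx(1.0)
    assert report.invariance_jaccard == 1.0
    row = report.to_row()
    again = FaithfulnessReport(
        dataset=row["dataset"],
        model=row["model"],
        method=row["method"],
        monotonicity_rho=row["monotonicity"],
        invariance_jaccard=row["implementation_invariance"],
        k=row["k"],
        n_seeds=row["n_seeds"],
        n_instances=row["n_instances"],
        expected_source=row["expected_source"],
    )
    assert again == report


def test_report_bounds_validated():
    with pytest.raises(ValueError):
        FaithfulnessReport("d", "m", "lime", 1.5, 0.5, 5, 5, 10)
    with pytest.raises(ValueError):
        FaithfulnessReport("d", "m", "lime", 0.5, -0.1, 5, 5, 10)
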