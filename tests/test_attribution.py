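"""Shapley values against a permutation oracle, LIME against direct solvers."""

import math
from itertools import permutations

import numpy as np
import pytest

from diaglass.attribution import (
    AttributionError,
    AttributionVector,
    LimeConfig,
    ShapleyConfig,
    _coalition_value,
    global_importance,
    lime_explain,
    proximity_weight,
    shapley_explain,
    shapley_value,
    top_k,
)


def permutation_oracle(predict, x, background):
    """Brute-force Shapley: average marginal contribution over all d! orders."""
    d = len(x)
    phi = np.zeros(d)
    for perm in permutations(range(d)):
        current = []
        prev = _coalition_value(predict, x, current, background)
        for j in perm:
            current = current + [j]
            cur = _coalition_value(predict, x, sorted(current), background)
            phi[j] += cur - prev
            prev = cur
    return phi / math.factorial(d)


def toy_value_functions():
    rng = np.random.default_rng(42)
    w3 = np.array([1.5, -2.0, 0.7])
    w5 = rng.normal(size=5)
    return [
        ("and3", lambda X: (X[:, 0] > 0.5) * (X[:, 1] > 0.5) * (0.5 + X[:, 2]), 3),
        ("linear3", lambda X: X @ w3, 3),
        ("interact5", lambda X: X @ w5 + 0.8 * X[:, 0] * X[:, 1] - X[:, 2] ** 2, 5),
        (
            "max6",
            lambda X: np.max(X, axis=1) + 0.3 * np.min(X, axis=1),
            6,
        ),
    ]


@pytest.mark.parametrize(
    "name,f,d", toy_value_functions(), ids=[v[0] for v in toy_value_functions()]
)
def test_exact_subset_formula_equals_permutation_enumeration(name, f, d):
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, size=d)
    bg = rng.uniform(0, 1, size=(8, d))
    cfg = ShapleyConfig(background=bg, mode="exact")
    phi = shapley_explain(f, x, cfg).weights
    oracle = permutation_oracle(f, x, bg)
    assert np.abs(phi - oracle).max() < 1e-12


def test_efficiency_axiom():
    rng = np.random.default_rng(2)
    f = lambda X: np.sin(X[:, 0]) + X[:, 1] * X[:, 2] - 0.5 * X[:, 3]
    x = rng.normal(size=4)
    bg = rng.normal(size=(20, 4))
    attr = shapley_explain(f, x, ShapleyConfig(background=bg, mode="exact"))
    total = attr.weights.sum()
    assert total == pytest.approx(float(f(x[None, :])[0] - f(bg).mean()), abs=1e-9)


def test_symmetry_axiom():
    """Model and background symmetric in features 0, 1 -> equal attributions."""
    f = lambda X: X[:, 0] + X[:, 1] + 3 * X[:, 0] * X[:, 1] + X[:, 2]
    x = np.array([0.7, 0.7, 0.2])
    bg = np.array([[0.1, 0.1, 0.5], [0.4, 0.4, 0.9]])
    attr = shapley_explain(f, x, ShapleyConfig(background=bg, mode="exact"))
    assert attr.weights[0] == pytest.approx(attr.weights[1], abs=1e-9)


def test_dummy_axiom():
    f = lambda X: X[:, 0] * 2.0 + 0.0 * X[:, 1]
    rng = np.random.default_rng(3)
    attr = shapley_explain(
        f,
        rng.normal(size=2),
        ShapleyConfig(background=rng.normal(size=(10, 2)), mode="exact"),
    )
    assert attr.weights[1] == pytest.approx(0.0, abs=1e-9)


def test_linearity_axiom():
    rng = np.random.default_rng(4)
    f = lambda X: X[:, 0] * X[:, 1]
    g = lambda X: np.cos(X[:, 2]) + X[:, 0]
    x = rng.normal(size=3)
    bg = rng.normal(size=(15, 3))
    cfg = ShapleyConfig(background=bg, mode="exact")
    pf = shapley_explain(f, x, cfg).weights
    pg = shapley_explain(g, x, cfg).weights
    pfg = shapley_explain(lambda X: f(X) + g(X), x, cfg).weights
    assert np.abs(pfg - (pf + pg)).max() < 1e-9


def test_constant_model_all_zero():
    f = lambda X: np.full(len(X), 0.37)
    attr = shapley_explain(
        f, np.ones(4), ShapleyConfig(background=np.zeros((5, 4)), mode="exact")
    )
    assert np.abs(attr.weights).max() < 1e-12


@pytest.mark.parametrize("d", [3, 7, 10])
def test_additive_model_closed_form(d):
    """phi_j = w_j (x_j - mean background_j) for any additive model."""
    rng = np.random.default_rng(d)
    w = rng.normal(size=d)
    x = rng.normal(size=d)
    bg = rng.normal(size=(30, d))
    attr = shapley_explain(
        lambda X: X @ w + 1.0, x, ShapleyConfig(background=bg, mode="exact")
    )
    assert np.abs(attr.weights - w * (x - bg.mean(axis=0))).max() < 1e-9


def test_exact_mode_dimension_guard():
    with pytest.raises(AttributionError, match="sampled"):
        shapley_explain(
            lambda X: X.sum(axis=1),
            np.zeros(16),
            ShapleyConfig(background=np.zeros((2, 16)), mode="exact"),
        )


def test_sampled_converges_to_exact():
    f = lambda X: (X[:, 0] > 0.5) * (X[:, 1] > 0.5) * (0.5 + 0.5 * (X[:, 2] > 0.5))
    x = np.ones(3)
    bg = np.zeros((1, 3))
    exact = shapley_explain(f, x, ShapleyConfig(background=bg, mode="exact")).weights
    sampled = shapley_explain(
        f, x, ShapleyConfig(background=bg, mode="sampled", n_permutations=5000, seed=2)
    ).weights
    assert np.abs(exact - sampled).max() < 0.01


def test_shapley_value_single_feature_matches_full():
    rng = np.random.default_rng(7)
    f = lambda X: X[:, 0] * X[:, 1] + X[:, 2]
    x = rng.normal(size=3)
    cfg = ShapleyConfig(background=rng.normal(size=(10, 3)), mode="exact")
    full = shapley_explain(f, x, cfg).weights
    assert shapley_value(f, x, 1, cfg) == pytest.approx(full[1], abs=1e-12)


def test_global_importance_is_mean_abs():
    rng = np.random.default_rng(8)
    w = np.array([2.0, -1.0])
    f = lambda X: X @ w
    rows = rng.normal(size=(4, 2))
    bg = rng.normal(size=(10, 2))
    cfg = ShapleyConfig(background=bg, mode="exact")
    gl = global_importance(f, rows, cfg)
    expected = np.mean(
        [np.abs(w * (x - bg.mean(axis=0))) for x in rows], axis=0
    )
    assert np.allclose(gl.weights, expected, atol=1e-9)
    assert gl.instance_ref == "global"


def test_sampled_bitwise_reproducible():
    rng = np.random.default_rng(9)
    f = lambda X: X.prod(axis=1)
    x = rng.normal(size=4)
    cfg = dict(background=rng.normal(size=(10, 4)), mode="sampled", n_permutations=50, seed=5)
    a = shapley_explain(f, x, ShapleyConfig(**cfg)).weights
    b = shapley_explain(f, x, ShapleyConfig(**cfg)).weights
    assert np.array_equal(a, b)


# -- LIME ------------------------------------------------------------------

def test_kernel_is_one_at_origin():
    assert proximity_weight(0.0, 2.0) == 1.0


def test_lime_recovers_linear_black_box():
    w = np.array([2.0, -1.5, 0.8, 0.3])
    f = lambda X: X @ w + 0.7
    attr = lime_explain(
        f,
        np.ones(4),
        ["continuous"] * 4,
        LimeConfig(n_perturbations=10_000, seed=0, regularization=1e-6),
    )
    rel = np.abs(attr.weights - w) / np.abs(w)
    assert rel.max() < 0.05
    assert attr.baseline_value == pytest.approx(0.7, rel=0.05)


def test_lime_matches_independent_ridge_solver():
    """Closed-form weighted fit equals sklearn's ridge to 1e-8."""
    from sklearn.linear_model import Ridge

    from diaglass.attribution import _perturb, _weighted_ridge

    cfg = LimeConfig(n_perturbations=500, seed=4, regularization=1e-3)
    x = np.ones(4)
    rng = np.random.default_rng(cfg.seed)
    Z = _perturb(x, ["continuous"] * 4, cfg, rng)
    y = Z @ np.array([1.0, 2.0, -0.5, 0.0]) + 0.1 * np.sin(3 * Z[:, 0])
    w = np.exp(-np.sum((Z - x) ** 2, axis=1) / (0.75 * 2) ** 2)
    coef, intercept, _ = _weighted_ridge(Z, y, w, cfg.regularization)
    ref = Ridge(alpha=cfg.regularization).fit(Z, y, sample_weight=w)
    assert np.abs(coef - ref.coef_).max() < 1e-8
    assert abs(intercept - ref.intercept_) < 1e-8


def test_lime_binary_features_flip():
    calls = {}

    def f(X):
        calls["Z"] = X.copy()
        return X[:, 0] * 1.0

    x = np.array([1.0, 0.0])
    lime_explain(f, x, ["binary", "binary"], LimeConfig(n_perturbations=200, seed=1))
    Z = calls["Z"]
    assert set(np.unique(Z)) <= {0.0, 1.0}
    assert 0 < (Z[:, 0] == 0.0).sum() < 200  # some flips, not all


def test_lime_singular_design_rejected():
    f = lambda X: X[:, 0]
    cfg = LimeConfig(n_perturbations=50, seed=0, perturbation_scale=0.0)
    with pytest.raises(AttributionError, match="singular"):
        lime_explain(f, np.zeros(3), ["continuous"] * 3, cfg)


def test_lime_bitwise_reproducible():
    f = lambda X: X @ np.array([1.0, -1.0])
    cfg = LimeConfig(n_perturbations=100, seed=3)
    a = lime_explain(f, np.zeros(2), ["continuous"] * 2, cfg).weights
    b = lime_explain(f, np.zeros(2), ["continuous"] * 2, cfg).weights
    assert np.array_equal(a, b)


def test_lime_min_perturbations():
    with pytest.raises(ValueError):
        lime_explain(
            lambda X: X[:, 0],
            np.zeros(5),
            ["continuous"] * 5,
            LimeConfig(n_perturbations=4),
        )


# -- top-k -----------------------------------------------------------------

def test_top_k_ordering_and_ties():
    attr = AttributionVector(
        ["bmi", "glucose", "age"], np.array([0.9, 0.5, 0.1]), method="lime"
    )
    assert top_k(attr, 2) == ["bmi", "glucose"]
    flat = AttributionVector(
        ["c", "a", "b"], np.array([0.3, 0.3, 0.3]), method="lime"
    )
    assert top_k(flat, 3) == ["a", "b", "c"]
    assert sorted(top_k(attr, 3)) == ["age", "bmi", "glucose"]
    with pytest.raises(ValueError):
        top_k(attr, 0)
    with pytest.raises(ValueError):
        top_k(attr, 4)
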