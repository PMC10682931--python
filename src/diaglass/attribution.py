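"""Feature attribution from first principles: Shapley values, LIME, S-LIME.

Shapley values use the interventional value function

    v(S) = mean over background rows b of  f(x_S, b_{F \\ S})

i.e. features in the coalition S are pinned to the explained instance and
the rest are drawn from a background sample.  Exact mode enumerates all
subsets S of F minus {j} with the combinatorial weight
|S|! (d - |S| - 1)! / d!; sampled mode averages marginal contributions over
seeded random permutations.  The exact enumeration is limited to d <= 15.

LIME fits a proximity-weighted ridge surrogate to the model's positive-class
probability on perturbed copies of one instance: continuous features get
Gaussian noise in scaled space, binary features independent flips.  The
proximity kernel is exp(-D(x, z)^2 / sigma^2) with Euclidean D in scaled
space.  The surrogate is solved in closed form (penalized weighted normal
equations with an unpenalized intercept), which also yields the coefficient
covariance needed by the stability procedure.

S-LIME-style stability: run two independent perturbation batches, rank
features by pooled mean |coefficient|, and z-test the gap between the k-th
and (k+1)-th coefficient magnitudes using the analytic sampling variances;
double the perturbation count until the ranking boundary is significant at
level alpha (or a cap is reached), then report the mean pairwise Jaccard of
top-k sets over five independent runs at the chosen count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .table import BINARY, CONTINUOUS


class AttributionError(Exception):
    pass


@dataclass
class AttributionVector:
    feature_names: list[str]
    weights: np.ndarray
    method: str  # shapley_exact | shapley_sampled | lime
    instance_ref: object = "global"
    baseline_value: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_names),):
            raise ValueError("weights length must match feature count")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")


def top_k(attr: AttributionVector, k: int) -> list[str]:
    """The k features with largest |weight|; ties by lexicographic name."""
    d = len(attr.feature_names)
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}]")
    order = sorted(
        range(d), key=lambda j: (-abs(attr.weights[j]), attr.feature_names[j])
    )
    return [attr.feature_names[j] for j in order[:k]]


# -- Shapley ---------------------------------------------------------------

@dataclass
class ShapleyConfig:
    background: np.ndarray
    mode: str = "exact"
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.background = np.atleast_2d(np.asarray(self.background, dtype=float))
        if self.background.shape[0] == 0:
            raise ValueError("background must be non-empty")
        if self.mode not in ("exact", "sampled"):
            raise ValueError("mode must be 'exact' or 'sampled'")


def _coalition_value(predict, x, subset, background):
    """v(S): pin features in S to x, draw the rest from the background."""
    comp = background.copy()
    if subset:
        comp[:, list(subset)] = x[list(subset)]
    return float(np.mean(predict(comp)))


class _ValueCache:
    def __init__(self, predict, x, background):
        self.predict = predict
        self.x = x
        self.background = background
        self._cache: dict[frozenset, float] = {}

    def __call__(self, subset) -> float:
        key = frozenset(subset)
        if key not in self._cache:
            self._cache[key] = _coalition_value(
                self.predict, self.x, sorted(key), self.background
            )
        return self._cache[key]


def shapley_value(predict, x, j: int, config: ShapleyConfig) -> float:
    """phi_j for one feature of one instance."""
    return shapley_explain(predict, x, config, features=[j]).weights[0]


def shapley_explain(
    predict, x, config: ShapleyConfig, feature_names=None, features=None
) -> AttributionVector:
    """Shapley attribution of ``predict`` at instance ``x``.

    ``predict`` maps an (n, d) matrix to an (n,) vector (for classifiers,
    the positive-class probability).  In exact mode all 2^(d-1) coalitions
    per feature are enumerated through a shared value cache; sampled mode
    averages marginal contributions along seeded random permutations.
    """
    x = np.asarray(x, dtype=float).ravel()
    d = x.shape[0]
    if config.background.shape[1] != d:
        raise ValueError("background width must match the instance")
    targets = list(range(d)) if features is None else list(features)
    v = _ValueCache(predict, x, config.background)

    if config.mode == "exact":
        if d > 15:
            raise AttributionError(
                f"exact enumeration infeasible for d={d} > 15; use mode='sampled'"
            )
        phi = np.zeros(len(targets))
        fact = [math.factorial(i) for i in range(d + 1)]
        for t, j in enumerate(targets):
            rest = [i for i in range(d) if i != j]
            total = 0.0
            for size in range(d):
                w = fact[size] * fact[d - size - 1] / fact[d]
                for S in combinations(rest, size):
                    total += w * (v(set(S) | {j}) - v(S))
            phi[t] = total
    else:
        rng = np.random.default_rng(config.seed)
        phi_full = np.zeros(d)
        for _ in range(config.n_permutations):
            perm = rng.permutation(d)
            before = v(())
            current: set[int] = set()
            for j in perm:
                current.add(int(j))
                after = v(current)
                phi_full[j] += after - before
                before = after
        phi_full /= config.n_permutations
        phi = phi_full[targets]

    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in targets]
    )
    if features is not None and feature_names is None:
        names = [f"x{j}" for j in targets]
    return AttributionVector(
        feature_names=names,
        weights=phi,
        method=f"shapley_{config.mode}",
        instance_ref="instance",
        baseline_value=v(()),
    )


def global_importance(
    predict, rows: np.ndarray, config: ShapleyConfig, feature_names=None
) -> AttributionVector:
    """Mean |phi_j| over the supplied rows: the global feature ranking."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    mags = np.zeros(rows.shape[1])
    for x in rows:
        mags += np.abs(shapley_explain(predict, x, config).weights)
    mags /= rows.shape[0]
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(rows.shape[1])]
    )
    return AttributionVector(
        feature_names=names,
        weights=mags,
        method=f"shapley_{config.mode}",
        instance_ref="global",
    )


# -- LIME ------------------------------------------------------------------

@dataclass
class LimeConfig:
    n_perturbations: int = 1000
    kernel_width: float | None = None  # default 0.75*sqrt(d), set at fit time
    regularization: float = 1e-3
    seed: int = 0
    perturbation_scale: float = 1.0
    flip_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.kernel_width is not None and self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.regularization < 0:
            raise ValueError("regularization must be nonnegative")


def _perturb(x, schema, config: LimeConfig, rng) -> np.ndarray:
    Z = np.tile(x, (config.n_perturbations, 1))
    for j, kind in enumerate(schema):
        if kind == CONTINUOUS:
            Z[:, j] += rng.normal(
                0.0, config.perturbation_scale, size=config.n_perturbations
            )
        elif kind == BINARY:
            flips = rng.uniform(size=config.n_perturbations) < config.flip_probability
            Z[flips, j] = 1.0 - Z[flips, j]
    return Z


def _weighted_ridge(Z, y, w, lam):
    """Penalized weighted least squares with an unpenalized intercept.

    Returns (coef, intercept, coef covariance).  Covariance is the sandwich
    sigma^2 A^-1 X'W^2X A^-1 with A = X'WX + Lambda, the CLT-scale estimate
    the stability test consumes.
    """
    n, d = Z.shape
    X = np.column_stack([np.ones(n), Z])
    P = np.diag([0.0] + [lam] * d)
    XtW = X.T * w
    A = XtW @ X + P
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise AttributionError(
            "singular weighted design: perturbations carry no variation"
        )
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (XtW @ y)
    resid = y - X @ beta
    sigma2 = float(np.sum(w * resid**2) / np.sum(w))
    cov = sigma2 * (Ainv @ (X.T * w**2) @ X @ Ainv)
    return beta[1:], float(beta[0]), cov[1:, 1:]


def lime_explain(
    predict, x, schema, config: LimeConfig, feature_names=None, _return_cov=False
):
    """Local surrogate explanation of ``predict`` at instance ``x``.

    ``predict`` maps (n, d) to the (n,) positive-class probability; ``x``
    is assumed to live in the same scaled space the model was trained in.
    """
    x = np.asarray(x, dtype=float).ravel()
    d = x.shape[0]
    if len(schema) != d:
        raise ValueError("schema length must match the instance")
    if config.n_perturbations < d + 2:
        raise ValueError("n_perturbations must be at least d + 2")
    sigma = config.kernel_width or 0.75 * np.sqrt(d)
    rng = np.random.default_rng(config.seed)
    Z = _perturb(x, schema, config, rng)
    if np.ptp(Z, axis=0).max() == 0.0:
        raise AttributionError(
            "singular weighted design: all perturbations are identical"
        )
    y = np.asarray(predict(Z), dtype=float).ravel()
    dist2 = np.sum((Z - x) ** 2, axis=1)
    w = np.exp(-dist2 / sigma**2)
    coef, intercept, cov = _weighted_ridge(Z, y, w, config.regularization)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(d)]
    )
    attr = AttributionVector(
        feature_names=names,
        weights=coef,
        method="lime",
        instance_ref="instance",
        baseline_value=intercept,
    )
    return (attr, cov) if _return_cov else attr


def proximity_weight(dist: float, sigma: float) -> float:
    """The LIME kernel pi(z) = exp(-D^2 / sigma^2); equals 1 at D = 0."""
    return float(np.exp(-(dist**2) / sigma**2))


# -- S-LIME-style stability -------------------------------------------------

@dataclass
class StabilityReport:
    n_required: int
    topk_jaccard_across_runs: float
    alpha: float
    stability_reached: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.topk_jaccard_across_runs <= 1.0:
            raise ValueError("jaccard must be in [0, 1]")


def _pairwise_jaccard(sets) -> float:
    pairs = [
        len(a & b) / len(a | b)
        for i, a in enumerate(sets)
        for b in sets[i + 1 :]
    ]
    return float(np.mean(pairs)) if pairs else 1.0


def slime_stability(
    predict,
    x,
    schema,
    config: LimeConfig,
    alpha: float = 0.05,
    k: int = 5,
    max_doublings: int = 6,
    feature_names=None,
) -> StabilityReport:
    """Choose a perturbation count that makes the top-k ranking stable.

    At each stage two independent batches of ``n`` perturbations are fitted;
    the boundary features (rank k vs k+1 by pooled mean |coefficient|) are
    z-tested using the analytic coefficient variances of both batches.  The
    count doubles until the boundary gap is significant at ``alpha`` or
    ``max_doublings`` is exhausted (reported via ``stability_reached``).
    ``k = d`` makes the boundary test vacuous and keeps the initial count.
    """
    x = np.asarray(x, dtype=float).ravel()
    d = x.shape[0]
    if k > d:
        raise ValueError("k must not exceed the feature count")
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(d)
    ]
    n = config.n_perturbations
    reached = k == d
    z_crit = stats.norm.ppf(1 - alpha)

    if k < d:
        for stage in range(max_doublings + 1):
            batches = []
            for b in range(2):
                cfg = LimeConfig(
                    n_perturbations=n,
                    kernel_width=config.kernel_width,
                    regularization=config.regularization,
                    seed=config.seed + 1000 * stage + b,
                    perturbation_scale=config.perturbation_scale,
                    flip_probability=config.flip_probability,
                )
                attr, cov = lime_explain(
                    predict, x, schema, cfg, feature_names=names, _return_cov=True
                )
                batches.append((np.abs(attr.weights), np.diag(cov)))
            pooled = (batches[0][0] + batches[1][0]) / 2.0
            order = np.argsort(-pooled)
            i_k, i_k1 = order[k - 1], order[k]
            theta = np.mean([m[i_k] - m[i_k1] for m, _ in batches])
            var = sum(v[i_k] + v[i_k1] for _, v in batches) / 4.0
            z = theta / np.sqrt(var) if var > 0 else np.inf
            if z > z_crit:
                reached = True
                break
            if stage < max_doublings:
                n *= 2
        # loop exit with reached=False means the cap was hit

    sets = []
    for run in range(5):
        cfg = LimeConfig(
            n_perturbations=n,
            kernel_width=config.kernel_width,
            regularization=config.regularization,
            seed=config.seed + 77_000 + run,
            perturbation_scale=config.perturbation_scale,
            flip_probability=config.flip_probability,
        )
        attr = lime_explain(predict, x, schema, cfg, feature_names=names)
        sets.append(set(top_k(attr, k)))
    return StabilityReport(
        n_required=n,
        topk_jaccard_across_runs=_pairwise_jaccard(sets),
        alpha=alpha,
        stability_reached=reached,
    )
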