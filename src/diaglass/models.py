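"""The three risk predictors — decision tree, random forest, feed-forward net.

Trees use entropy (information gain) impurity and store leaf class
frequencies, so every model emits class probabilities rather than bare
labels.  The forest is bagging over the same entropy trees with a random
feature subset per split (default sqrt(d)); with one tree, bootstrapping
disabled and all features considered it reduces to the single tree trainer
by construction.  The network is a small fully-connected net (default
hidden sizes 16 and 8, sigmoid activations, 2-unit softmax output) trained
with mini-batch gradient descent on the cross-entropy loss; initialization
and batch order are fully determined by the seed.

Every trainer returns ``(model, TrainedModelCard)`` so the fitted instance
can be registered into the knowledge graph for provenance queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    auc,
    precision_recall_curve,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.tree import DecisionTreeClassifier

from .kg import TrainedModelCard
from .table import FeatureTable


class ModelError(Exception):
    pass


def entropy(counts) -> float:
    """Shannon entropy in bits of a class-count (or probability) vector."""
    p = np.asarray(counts, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("counts must have a positive sum")
    p = p[p > 0] / total
    return float(-(p * np.log2(p)).sum())


@dataclass
class PredictionResult:
    probabilities: tuple[float, float]
    predicted_class: int
    model_id: str


# -- decision tree --------------------------------------------------------

@dataclass
class TreeModel:
    model_id: str
    feature_names: list[str]
    tree: DecisionTreeClassifier
    classes_: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        raw = self.tree.predict_proba(X)
        return _expand_proba(raw, self.classes_)


def _expand_proba(raw: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Map a classifier's per-known-class probabilities onto columns (0, 1)."""
    out = np.zeros((raw.shape[0], 2))
    for col, cls in enumerate(classes):
        out[:, int(cls)] = raw[:, col]
    return out


def train_decision_tree(
    train: FeatureTable,
    max_depth: int | None = None,
    min_leaf: int = 1,
    seed: int = 0,
) -> tuple[TreeModel, TrainedModelCard]:
    """Greedy entropy (information-gain) tree with frequency leaves.

    A single-class training set yields the degenerate stump predicting that
    class with probability 1.
    """
    tree = DecisionTreeClassifier(
        criterion="entropy",
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=seed,
    )
    tree.fit(train.X, train.y)
    model = TreeModel(
        model_id=f"dt_seed{seed}",
        feature_names=list(train.feature_names),
        tree=tree,
        classes_=tree.classes_,
    )
    card = TrainedModelCard(
        model_id=model.model_id,
        algorithm_name="decision_tree",
        dataset_ref="",
        seed=seed,
        hyperparameters={"max_depth": max_depth, "min_samples_leaf": min_leaf,
                         "criterion": "entropy"},
    )
    return model, card


# -- random forest --------------------------------------------------------

@dataclass
class ForestModel:
    model_id: str
    feature_names: list[str]
    trees: list[TreeModel] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.mean([t.predict_proba(X) for t in self.trees], axis=0)


def train_random_forest(
    train: FeatureTable,
    n_trees: int = 100,
    max_features: int | str | None = "sqrt",
    seed: int = 0,
    bootstrap: bool = True,
    max_depth: int | None = None,
) -> tuple[ForestModel, TrainedModelCard]:
    """Bagged entropy trees with a random feature subset per split.

    Tree ``i`` uses seed ``seed + i`` for its split randomness and an
    independent bootstrap resample; with ``n_trees=1, bootstrap=False,
    max_features=None`` this is exactly :func:`train_decision_tree`.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    trees = []
    for i in range(n_trees):
        if bootstrap:
            idx = rng.integers(train.n, size=train.n)
            sub = train.subset(idx)
            # a bootstrap that lost a class would break the probability map;
            # resample until both classes are present (tiny-n corner)
            while min(sub.class_counts()) == 0 and min(train.class_counts()) > 0:
                idx = rng.integers(train.n, size=train.n)
                sub = train.subset(idx)
        else:
            sub = train
        clf = DecisionTreeClassifier(
            criterion="entropy",
            max_features=max_features,
            max_depth=max_depth,
            random_state=seed + i,
        )
        clf.fit(sub.X, sub.y)
        trees.append(
            TreeModel(
                model_id=f"rf_seed{seed}_tree{i}",
                feature_names=list(train.feature_names),
                tree=clf,
                classes_=clf.classes_,
            )
        )
    model = ForestModel(
        model_id=f"rf_seed{seed}", feature_names=list(train.feature_names), trees=trees
    )
    card = TrainedModelCard(
        model_id=model.model_id,
        algorithm_name="random_forest",
        dataset_ref="",
        seed=seed,
        hyperparameters={
            "n_trees": n_trees,
            "max_features": str(max_features),
            "bootstrap": bootstrap,
            "criterion": "entropy",
        },
    )
    return model, card


# -- feed-forward network -------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class NeuralNetModel:
    model_id: str
    feature_names: list[str]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_history: list[float] = field(default_factory=list)

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [np.atleast_2d(np.asarray(X, dtype=float))]
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            acts.append(_softmax(z) if i == last else _sigmoid(z))
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]


def init_network(
    n_features: int, hidden_sizes=(16, 8), seed: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Seeded Gaussian init scaled by 1/sqrt(fan_in); output layer has 2 units."""
    rng = np.random.default_rng(seed)
    sizes = [n_features, *hidden_sizes, 2]
    weights = [
        rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b))
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    biases = [np.zeros(b) for b in sizes[1:]]
    return weights, biases


def cross_entropy(proba: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(proba[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def train_dnn(
    train: FeatureTable,
    hidden_sizes=(16, 8),
    epochs: int = 300,
    learning_rate: float = 0.5,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[NeuralNetModel, TrainedModelCard]:
    """Mini-batch gradient descent on the softmax cross-entropy loss.

    Features are assumed already scaled.  All randomness (initial weights,
    batch order) derives from ``seed``; identical seeds give bitwise
    identical initial weights and per-epoch losses.  A non-finite loss
    aborts with diagnostics.
    """
    weights, biases = init_network(train.d, hidden_sizes, seed)
    model = NeuralNetModel(
        model_id=f"dnn_seed{seed}",
        feature_names=list(train.feature_names),
        weights=weights,
        biases=biases,
    )
    rng = np.random.default_rng(seed + 1)
    Y = np.eye(2)[train.y]
    for epoch in range(epochs):
        order = rng.permutation(train.n)
        for start in range(0, train.n, batch_size):
            idx = order[start : start + batch_size]
            acts = model.forward(train.X[idx])
            delta = (acts[-1] - Y[idx]) / len(idx)  # softmax + CE gradient
            for layer in range(len(model.weights) - 1, -1, -1):
                grad_W = acts[layer].T @ delta
                grad_b = delta.sum(axis=0)
                if layer > 0:
                    a = acts[layer]
                    delta = (delta @ model.weights[layer].T) * a * (1.0 - a)
                model.weights[layer] -= learning_rate * grad_W
                model.biases[layer] -= learning_rate * grad_b
        loss = cross_entropy(model.predict_proba(train.X), train.y)
        if not np.isfinite(loss):
            raise ModelError(
                f"non-finite loss at epoch {epoch}; "
                f"lr={learning_rate}, hidden={hidden_sizes}"
            )
        model.loss_history.append(loss)
    card = TrainedModelCard(
        model_id=model.model_id,
        algorithm_name="dnn",
        dataset_ref="",
        seed=seed,
        hyperparameters={
            "hidden_sizes": list(hidden_sizes),
            "epochs": epochs,
            "learning_rate": learning_rate,
            "batch_size": batch_size,
            "activation": "sigmoid",
            "output": "softmax",
            "loss": "cross_entropy",
        },
    )
    return model, card


# -- prediction & evaluation ----------------------------------------------

def predict_proba(model, rows: np.ndarray) -> list[PredictionResult]:
    """Per-row class probabilities; argmax ties go to the positive class."""
    proba = model.predict_proba(np.atleast_2d(rows))
    results = []
    for p in proba:
        cls = 1 if p[1] >= p[0] else 0
        results.append(
            PredictionResult(
                probabilities=(float(p[0]), float(p[1])),
                predicted_class=cls,
                model_id=model.model_id,
            )
        )
    return results


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict
    roc_points: list[tuple[float, float]]
    auc: float
    pr_points: list[tuple[float, float]]

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray) -> EvalReport:
    """Metrics from positive-class scores: pure function of (y_true, scores).

    Class assignment thresholds the score at 0.5; headline
    precision/recall/F1 are macro averages with per-class values alongside;
    ROC sweeps the unique scores and AUC is the trapezoid integral.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= 0.5).astype(int)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    pc_prec, pc_rec, pc_f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    fpr, tpr, _ = roc_curve(y_true, scores)
    p_curve, r_curve, _ = precision_recall_curve(y_true, scores)
    return EvalReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        per_class={
            "precision": pc_prec.tolist(),
            "recall": pc_rec.tolist(),
            "f1": pc_f1.tolist(),
            "support": support.tolist(),
        },
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=float(auc(fpr, tpr)),
        pr_points=list(zip(r_curve.tolist(), p_curve.tolist())),
    )


def evaluate(model, test: FeatureTable) -> EvalReport:
    if model.feature_names != list(test.feature_names):
        raise ModelError(
            "feature schema mismatch between model and evaluation table"
        )
    return evaluate_scores(test.y, model.predict_proba(test.X)[:, 1])
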