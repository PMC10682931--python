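"""Synthetic cohorts, a toy diabetes knowledge graph, and toy embeddings.

Two cohort generators emulate the statistical shape of the field's standard
diabetes benchmarks, with *planted* effect sizes so that ground-truth
feature importances are known:

* Pima-style — 8 continuous clinical features (glucose, BMI, ...) for 768
  women, ~35% positive; outcomes follow a logistic model on z-scored
  features, with the intercept tuned by bisection so the realized positive
  fraction hits the target.
* Early-stage-style — 14 binary symptom features (polyuria, polydipsia,
  ..., alopecia) plus age and sex for 520 people with exactly the 200/320
  healthy/patient split; symptoms are class-conditional Bernoulli with a
  log-odds gap equal to the planted coefficient, so the Bayes-optimal
  logistic coefficient of each symptom equals the planted value.

The planted coefficient of feature j times its realized standard deviation,
|c_j| * sd_j, is the expected-importance oracle used by the faithfulness
metrics.  Both generators are pure functions of their spec (including the
seed).  Feature correlations default to independence.

The toy knowledge graph carries an entity card (label, synonyms, non-empty
definition, external link) for every default feature of both cohorts, plus
disease, examination, dataset and algorithm entities and relation triples.
The toy embedding index places each concept's tokens on a shared "diabetes
domain" direction plus a concept-specific orthogonal anchor, giving
within-concept cosine ~1 and cross-concept cosine ~0.45 — enough structure
for the entity matcher to resolve every feature and planted synonym.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .embeddings import EmbeddingIndex, tokenize
from .kg import EntityCard, KnowledgeGraph
from .table import BINARY, CONTINUOUS, FeatureTable

PIMA_FEATURES = [
    "pregnancies",
    "glucose",
    "blood_pressure",
    "skin_thickness",
    "insulin",
    "bmi",
    "pedigree",
    "age",
]

# (mean, sd) of the truncated-at-zero Gaussians, chosen to resemble the
# published summary statistics of the real cohort
PIMA_MOMENTS = {
    "pregnancies": (3.8, 3.4),
    "glucose": (121.0, 31.0),
    "blood_pressure": (69.0, 19.0),
    "skin_thickness": (21.0, 16.0),
    "insulin": (80.0, 100.0),
    "bmi": (32.0, 7.0),
    "pedigree": (0.47, 0.33),
    "age": (33.0, 12.0),
}

# logistic coefficients on z-scored features; glucose and BMI dominate
PIMA_COEFFICIENTS = {
    "glucose": 1.4,
    "bmi": 1.0,
    "age": 0.6,
    "pedigree": 0.45,
    "pregnancies": 0.35,
    "insulin": 0.25,
    "skin_thickness": 0.15,
    "blood_pressure": 0.1,
}

EARLYSTAGE_SYMPTOMS = [
    "polyuria",
    "polydipsia",
    "sudden_weight_loss",
    "weakness",
    "polyphagia",
    "genital_thrush",
    "visual_blurring",
    "itching",
    "irritability",
    "delayed_healing",
    "partial_paresis",
    "muscle_stiffness",
    "alopecia",
    "obesity",
]

EARLYSTAGE_FEATURES = ["age", "sex", *EARLYSTAGE_SYMPTOMS]

# class-conditional log-odds gaps; polyuria > polydipsia dominate
EARLYSTAGE_COEFFICIENTS = {
    "polyuria": 3.4,
    "polydipsia": 3.0,
    "sudden_weight_loss": 1.9,
    "partial_paresis": 1.7,
    "irritability": 1.4,
    "polyphagia": 1.2,
    "sex": -1.1,
    "visual_blurring": 1.05,
    "weakness": 0.9,
    "genital_thrush": 0.8,
    "muscle_stiffness": 0.7,
    "alopecia": -0.65,
    "age": 0.55,
    "itching": 0.5,
    "delayed_healing": 0.4,
    "obesity": 0.3,
}


@dataclass
class CohortSpec:
    """Everything a generator needs; a pure function of this spec + seed."""

    n: int
    feature_names: list[str]
    kinds: list[str]
    planted_coefficients: dict[str, float]
    means: dict[str, tuple[float, float]] = field(default_factory=dict)
    intercept: float | None = None  # None -> tuned by bisection
    positive_fraction: float = 0.35
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if not any(v != 0 for v in self.planted_coefficients.values()):
            raise ValueError("at least one planted coefficient must be nonzero")


def default_pima_spec(n: int = 768, seed: int = 7) -> CohortSpec:
    return CohortSpec(
        n=n,
        feature_names=list(PIMA_FEATURES),
        kinds=[CONTINUOUS] * len(PIMA_FEATURES),
        planted_coefficients=dict(PIMA_COEFFICIENTS),
        means=dict(PIMA_MOMENTS),
        positive_fraction=0.35,
        seed=seed,
    )


def default_earlystage_spec(n: int = 520, seed: int = 7) -> CohortSpec:
    kinds = [CONTINUOUS if f == "age" else BINARY for f in EARLYSTAGE_FEATURES]
    return CohortSpec(
        n=n,
        feature_names=list(EARLYSTAGE_FEATURES),
        kinds=kinds,
        planted_coefficients=dict(EARLYSTAGE_COEFFICIENTS),
        means={"age": (48.0, 12.0)},
        positive_fraction=320 / 520,
        seed=seed,
    )


def gen_pima_like(spec: CohortSpec | None = None) -> FeatureTable:
    """Pima-style cohort: truncated-Gaussian features, logistic outcome.

    The intercept is tuned by bisection on the *realized* positive fraction
    (with the feature matrix and uniform draws frozen, the fraction is a
    monotone step function of the intercept), so the target is met within
    the resolution 1/n, comfortably inside the +-2% contract.
    """
    spec = spec or default_pima_spec()
    if set(spec.feature_names) != set(PIMA_FEATURES) or len(spec.feature_names) != 8:
        raise ValueError("pima-style spec needs exactly the 8 continuous features")
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n, len(spec.feature_names)
    X = np.empty((n, d))
    for j, name in enumerate(spec.feature_names):
        mu, sd = spec.means[name]
        X[:, j] = truncnorm.rvs(
            (0.0 - mu) / sd, np.inf, loc=mu, scale=sd, size=n, random_state=rng
        )
    coef = np.array([spec.planted_coefficients.get(f, 0.0) for f in spec.feature_names])
    mu_vec = np.array([spec.means[f][0] for f in spec.feature_names])
    sd_vec = np.array([spec.means[f][1] for f in spec.feature_names])
    eta = ((X - mu_vec) / sd_vec) @ coef
    u = rng.uniform(size=n)

    if spec.intercept is not None:
        b0 = spec.intercept
    else:
        b0 = _bisect_intercept(eta, u, spec.positive_fraction)
    y = (u < expit(b0 + eta)).astype(int)
    frac = y.mean()
    if abs(frac - spec.positive_fraction) > 0.02:
        raise ValueError(
            f"positive fraction {frac:.3f} unattainable for target "
            f"{spec.positive_fraction:.3f}"
        )
    return FeatureTable(list(spec.feature_names), X, y, list(spec.kinds))


def _bisect_intercept(eta, u, target, lo=-20.0, hi=20.0, iters=80) -> float:
    """Realized fraction mean(u < sigmoid(b0 + eta)) is monotone in b0."""
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        if (u < expit(mid + eta)).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gen_earlystage_like(spec: CohortSpec | None = None) -> FeatureTable:
    """Early-stage-style cohort: class-conditional binary symptoms.

    Labels are assigned by a seeded shuffle of a fixed label vector with
    exactly round(n * positive_fraction) positives.  Each symptom j is
    Bernoulli with rates p0 = sigmoid(a_j - c_j/2), p1 = sigmoid(a_j +
    c_j/2), so its log odds ratio — the Bayes logistic coefficient — is
    exactly the planted c_j.  Age is Gaussian with a class shift of
    c_age * sd.
    """
    spec = spec or default_earlystage_spec()
    symptoms = [
        f for f, k in zip(spec.feature_names, spec.kinds) if k == BINARY
    ]
    if len(symptoms) < 14 + 1 or "age" not in spec.feature_names:
        # 14 symptoms + sex, plus continuous age
        raise ValueError(
            "early-stage-style spec needs >= 14 binary symptoms plus age and sex"
        )
    for required in ("polyuria", "polydipsia", "alopecia"):
        if required not in spec.feature_names:
            raise ValueError(f"missing required symptom feature {required!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_pos = int(round(n * spec.positive_fraction))
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_pos]] = 1

    X = np.empty((n, len(spec.feature_names)))
    base = logit(0.35)
    for j, (name, kind) in enumerate(zip(spec.feature_names, spec.kinds)):
        c = spec.planted_coefficients.get(name, 0.0)
        if kind == BINARY:
            rates = np.where(y == 1, expit(base + c / 2.0), expit(base - c / 2.0))
            X[:, j] = (rng.uniform(size=n) < rates).astype(float)
        else:
            mu, sd = spec.means.get(name, (48.0, 12.0))
            shift = c * sd
            X[:, j] = rng.normal(mu + shift * (y - 0.5), sd)
    return FeatureTable(list(spec.feature_names), X, y, list(spec.kinds))


def planted_importances(spec: CohortSpec, table: FeatureTable) -> dict[str, float]:
    """Ground-truth expected importances: |c_j| * sd_j in model (scaled) space.

    Planted coefficients act on z-scored continuous features (unit sd) and
    raw 0/1 binary features, so the expected magnitude of feature j's
    contribution is |c_j| for continuous features and |c_j| times the
    realized sd of the 0/1 column for binary ones.
    """
    sds = table.X.std(axis=0)
    out = {}
    for j, f in enumerate(table.feature_names):
        c = abs(spec.planted_coefficients.get(f, 0.0))
        if table.schema[j] == BINARY:
            out[f] = c * float(sds[j])
        else:
            out[f] = c
    return out


# -- toy knowledge graph ---------------------------------------------------

SYNONYMS = {
    "polyuria": ["frequent urination"],
    "polydipsia": ["thirst"],
    "polyphagia": ["overeating"],
    "weakness": ["fatigue"],
    "itching": ["pruritus"],
    "alopecia": ["balding"],
    "glucose": ["sugar"],
    "bmi": ["body mass index"],
    "pedigree": ["heredity"],
    "sex": ["gender"],
}

_DEFINITIONS = {
    "polyuria": "Production of abnormally large volumes of dilute urine; a cardinal early symptom of diabetes.",
    "polydipsia": "Excessive thirst persisting despite fluid intake, commonly accompanying polyuria.",
    "polyphagia": "Excessive hunger or increased appetite despite adequate food intake.",
    "sudden_weight_loss": "Unintentional rapid loss of body weight.",
    "weakness": "Generalized lack of physical strength or energy.",
    "genital_thrush": "Candidal infection of the genital mucosa, favored by glycosuria.",
    "visual_blurring": "Transient blurred vision caused by osmotic changes in the lens.",
    "itching": "Generalized pruritus of the skin.",
    "irritability": "Abnormal proneness to annoyance or anger.",
    "delayed_healing": "Slower than normal repair of wounds and skin lesions.",
    "partial_paresis": "Mild or partial muscle weakness affecting voluntary movement.",
    "muscle_stiffness": "Increased muscular tension and reduced flexibility.",
    "alopecia": "Loss of hair from areas where it normally grows; alopecia areata occurs more often in people with diabetes.",
    "obesity": "Excess body fat; body mass index of 30 or above.",
    "pregnancies": "Number of times the patient has been pregnant.",
    "glucose": "Plasma glucose concentration from an oral glucose tolerance test.",
    "blood_pressure": "Diastolic blood pressure in mm Hg.",
    "skin_thickness": "Triceps skinfold thickness in mm.",
    "insulin": "Two-hour serum insulin in mu U/ml.",
    "bmi": "Body mass index: weight in kg divided by height in m squared.",
    "pedigree": "Diabetes pedigree function summarizing family history of diabetes.",
    "age": "Age of the patient in years.",
    "sex": "Biological sex of the patient.",
    "diabetes": "A chronic metabolic disease marked by elevated blood glucose.",
    "lab_test": "A clinical laboratory examination performed on a patient sample.",
}

_ENTITY_TYPES = {
    **{s: "symptom" for s in EARLYSTAGE_SYMPTOMS},
    "pregnancies": "demographic",
    "glucose": "examination",
    "blood_pressure": "examination",
    "skin_thickness": "examination",
    "insulin": "examination",
    "bmi": "examination",
    "pedigree": "risk_factor",
    "age": "demographic",
    "sex": "demographic",
    "diabetes": "complication",
    "lab_test": "examination",
}

_EXAMINATION_FEATURES = ["glucose", "blood_pressure", "skin_thickness", "insulin", "bmi"]


def gen_toy_kg() -> KnowledgeGraph:
    """Toy diabetes KG covering every default feature of both cohorts."""
    kg = KnowledgeGraph()
    concepts = sorted(set(PIMA_FEATURES) | set(EARLYSTAGE_FEATURES))
    for cid in concepts + ["diabetes", "lab_test"]:
        kg.add_entity(
            EntityCard(
                entity_id=cid,
                label=cid.replace("_", " "),
                entity_type=_ENTITY_TYPES[cid],
                synonyms=list(SYNONYMS.get(cid, [])),
                definition=_DEFINITIONS[cid],
                external_link=f"https://example.org/medkb/{cid}",
            )
        )
    for ds, feats in (
        ("pima_cohort", PIMA_FEATURES),
        ("earlystage_cohort", EARLYSTAGE_FEATURES),
    ):
        kg.add_entity(
            EntityCard(
                entity_id=ds,
                label=ds.replace("_", " "),
                entity_type="dataset",
                definition=f"Synthetic cohort emulating the {ds.split('_')[0]} data shape.",
                external_link=f"https://example.org/datasets/{ds}",
            )
        )
        for f in feats:
            kg.add_triple(ds, "hasFeature", f)
    for algo in ("decision_tree", "random_forest", "dnn"):
        kg.add_entity(
            EntityCard(
                entity_id=algo,
                label=algo.replace("_", " "),
                entity_type="algorithm",
                definition=f"The {algo.replace('_', ' ')} learning algorithm.",
            )
        )
    for s in EARLYSTAGE_SYMPTOMS:
        kg.add_triple(s, "indicates", "diabetes")
    for f in _EXAMINATION_FEATURES:
        kg.add_triple(f, "measuredBy", "lab_test")
    for f in concepts:
        kg.add_triple(f, "associatedWith", "diabetes")
    return kg


def gen_toy_embeddings(dim: int = 32, seed: int = 0) -> EmbeddingIndex:
    """Clustered toy embeddings for the toy KG vocabulary.

    Every token of a concept (its id, label and synonyms) gets the vector
    0.9 * g + a_c + noise, where g is a shared domain axis and a_c a
    concept-specific orthogonal axis: within-concept cosine ~1, cross ~0.45.
    """
    if dim < 8:
        raise ValueError("dim must be at least 8")
    concepts = sorted(set(PIMA_FEATURES) | set(EARLYSTAGE_FEATURES)) + [
        "diabetes",
        "lab_test",
    ]
    if dim < len(concepts) + 1:
        raise ValueError(f"dim must be at least {len(concepts) + 1} for orthogonal anchors")
    token_concept: dict[str, str] = {}
    for cid in concepts:
        terms = [cid, cid.replace("_", " ")] + SYNONYMS.get(cid, [])
        for term in terms:
            for tok in tokenize(term):
                owner = token_concept.setdefault(tok, cid)
                if owner != cid:
                    raise ValueError(
                        f"token {tok!r} is claimed by both {owner!r} and {cid!r}"
                    )
    rng = np.random.default_rng(seed)
    anchor = {cid: i + 1 for i, cid in enumerate(concepts)}
    vectors = {}
    for tok, cid in token_concept.items():
        v = rng.normal(0.0, 0.02, size=dim)
        v[0] += 0.9
        v[anchor[cid]] += 1.0
        vectors[tok] = v
    return EmbeddingIndex(dimension=dim, vectors=vectors)
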