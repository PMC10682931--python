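# Methods

This note documents the models and procedures implemented in `diaglass`,
the defaults that matter, the numerical choices, and what the synthetic
cohorts do and do not establish.

## Prediction pipeline

**Scaling.** Continuous features are z-scored with the *population*
(divide-by-n) standard deviation, so fit-then-apply on the same rows yields
mean 0 and sd 1 exactly; a zero-variance column maps to all zeros. Binary
features (coded 0/1) pass through untouched and participate in all
Euclidean distances as 0/1 coordinates. Scaler parameters are always fitted
on the training split only.

**Rebalancing.** SMOTE synthesizes minority rows on segments between a
minority point and one of its k nearest minority neighbors (k defaults
to 5; k is clipped to minority−1 with a warning), with the interpolation
weight drawn Uniform[0, 1] and minority rows visited round-robin in a
seeded shuffled order. The default target is full balance. Tomek-link
cleaning then removes the *majority-class* member of every cross-class
mutual-1-NN pair, in a single pass (no iteration); when the classes are
tied in size the positive class is treated as the majority. The pipeline
order — scale, oversample, clean — is fixed because both neighbor-based
steps are only meaningful in scaled space. Rebalancing is configurable per
data set: the early-stage-shaped cohort (320/200) is mild enough that the
default study leaves it unbalanced, while the Pima-shaped cohort (~35%
positive) runs the full pipeline. Biologically impossible zeros in
Pima-style data are passed through by default; an optional median
imputation exists but is off for reproducibility.

**Models.** Decision tree and random-forest base trees are entropy
(information-gain) trees with class-frequency leaves (scikit-learn's
`criterion="entropy"`). The forest is bagging implemented in-package: tree
i gets seed `seed + i` and an independent bootstrap resample, with a random
feature subset per split (default √d); consequently one tree with
bootstrapping disabled and all features considered is *identical* to the
single-tree trainer, a property the tests exploit. The network is a
fully-connected net with default hidden sizes [16, 8], sigmoid hidden
activations and a 2-unit softmax output, trained by plain mini-batch
gradient descent on the cross-entropy loss (defaults: 300 epochs, batch
size 32, learning rate 0.5 — recorded in every model card). Whether a
"third" hidden layer should exist is left to the caller; `hidden_sizes` is
fully configurable. All initialization and batch order derive from the
seed: identical seeds give bitwise-identical initial weights and identical
per-epoch losses. A non-finite loss aborts with diagnostics rather than
returning a silently broken model.

**Evaluation.** Class assignment thresholds the positive-class probability
at 0.5, with argmax ties going to the positive class. Headline
precision/recall/F1 are macro averages; per-class values are always
attached. ROC sweeps the unique scores; AUC is the trapezoid integral; the
PR curve is computed analogously. `evaluate_scores` is a pure function of
`(y_true, scores)`.

## Attribution

**Shapley.** The coalition value is interventional: features in S are
pinned to the explained instance and the remainder drawn from a background
sample (recommended: a seeded sample of ≤100 training rows). Exact mode
enumerates all subsets through a shared value cache and is guarded at
d ≤ 15; sampled mode averages marginal contributions along seeded random
permutations and converges to the exact values (the tests require
agreement within 0.01 at 5000 permutations on a 3-feature oracle). The
exact implementation is verified against an independent full-permutation
enumeration to 1e-12 and satisfies efficiency, symmetry, dummy and
linearity to 1e-9. Global importance is the mean |φ| over supplied rows.

**LIME.** Perturbations are Gaussian noise (scale 1.0 by default) on
continuous features and independent flips (probability 0.3) on binary
features, all in scaled space. Proximity weights use
π(z) = exp(−D²/σ²) with σ = 0.75·√d by default. The surrogate is ridge
regression (λ = 1e−3 by default) on the positive-class probability, solved
in closed form via penalized weighted normal equations with an unpenalized
intercept — mathematically identical to scikit-learn's weighted `Ridge`,
which serves as the independent cross-check in the tests (agreement to
1e-8). The closed form also yields the analytic coefficient covariance
(sandwich estimator) consumed by the stability procedure. A perturbation
batch with no variation (e.g. zero noise scale on an all-continuous
schema) is rejected as a singular design.

**S-LIME-style stability.** The published stabilization idea is specified
only by citation, so the concrete procedure here is this package's
reading, documented as such: at each stage, fit two independent
perturbation batches of size n; rank features by pooled mean |coefficient|;
z-test the gap between the k-th and (k+1)-th magnitudes using each batch's
analytic coefficient variances (covariances between the two coefficients
are ignored — conservative for well-separated features); double n until
the boundary is significant at α (default 0.05) or a cap of 6 doublings is
reached, which is reported via a `stability_reached` flag. The report ends
with the mean pairwise Jaccard of top-k sets over 5 independent runs at
the chosen n. The "deterministic surrogate regime" in the tests is an
exactly linear, noise-free black box: there the surrogate recovers the
same coefficients from any batch, so the top-k Jaccard is exactly 1
regardless of the random draws (a literally zero perturbation scale would
instead be a singular design, which `lime_explain` rejects by contract).
With observation noise, the required n scales like 1/gap², so shrinking
the boundary gap never decreases n — a property the tests check across
three gap levels.

## Faithfulness metrics

Monotonicity is the Spearman correlation (average ranks for ties; constant
vectors rejected) between attribution *magnitudes* and expected
importances, so sign disagreements do not penalize and any strictly
increasing transform of either side is irrelevant. Expected importances
are an explicit argument with two natural providers: planted generative
coefficients on synthetic cohorts, or a model-derived oracle (e.g.
drop-column importance) on real data; the report records which was used.
Implementation invariance retrains the same architecture under different
seeds on identical data and averages the top-k Jaccard over unordered seed
pairs and evaluation instances (defaults: k = 5, 5 seeds). A
seed-independent pipeline scores exactly 1.

## Synthetic cohorts and what they show

The generators reproduce the *shape* of the two standard diabetes
benchmarks, not their exact marginal distributions: independent features,
no missing-data mechanism, no longitudinal structure.

- Pima-like: 8 truncated-Gaussian clinical features with moments close to
  the published summaries; outcome logistic in the z-scored features with
  planted coefficients (glucose 1.4 and BMI 1.0 dominant); the intercept
  is tuned by bisection *on the realized positive fraction with the draws
  frozen* (a monotone step function of the intercept), so the 35% target
  is met to within 1/n deterministically.
- Early-stage-like: labels assigned by seeded shuffle with exactly
  round(n·320/520) positives; each binary symptom is class-conditional
  Bernoulli with rates sigmoid(a ± c/2) around a base rate a = logit(0.35),
  so the symptom's log odds ratio — its Bayes-optimal logistic
  coefficient — is exactly the planted c (polyuria 3.4 > polydipsia 3.0
  dominate; alopecia and male sex planted negative). Age is Gaussian with
  a class shift of c·sd. Effect sizes were chosen to emulate the strong
  separability of the real symptom data set (where published forests reach
  ~0.99 accuracy); here the Bayes accuracy is ≈0.95 and a 100-tree forest
  holds ≥0.9 on a held-out fifth.

The expected-importance oracle is |c_j|·sd_j *on the model's input scale*:
|c_j| for z-scored continuous features, |c_j|·sd of the 0/1 column for
binary ones. A large-n logistic refit recovers this ordering with Spearman
ρ ≈ 0.99, which validates the oracle itself; LIME on a forest fitted to
the n=520 cohort reaches mean ρ ≈ 0.82–0.87 over 15 instances — the
residual gap is genuine locality of the explanations, not generator noise.
Passing these tests shows the machinery is correct and well-calibrated on
independent-feature logistic data; it does not certify behavior under
feature correlation or distribution shift (an optional correlation hook
exists for stress tests).

The faithfulness study sizes (15 evaluation instances, 2000 LIME
perturbations for monotonicity, 600 for the invariance sweep, 5 retraining
seeds, 100-tree forests) are the package's default study conditions,
chosen so the Monte-Carlo error of each metric is small relative to the
effects being measured.

## Toy knowledge graph and embeddings

Entity cards cover every default feature of both cohorts plus disease,
examination, dataset and algorithm entities; relation triples
(`indicates`, `measuredBy`, `associatedWith`, `hasFeature`) connect
features to the disease and dataset hubs, which is what gives the
depth-2 relation bonus its signal. The toy embedding index assigns every
token of a concept (id, label, synonyms) the vector 0.9·g + a_c + ε, with
g a shared domain axis, a_c a concept-specific orthogonal axis, and ε
small Gaussian noise: within-concept cosine ≈ 1, cross-concept ≈ 0.45.
Under the default evidence weights α = 0.6, β = 0.3, γ = 0.1 (label
similarity dominant; cosines affinely rescaled from [−1,1] to [0,1] so the
three terms are commensurable), every default feature then matches its own
entity with score ≥ 0.9 — by the cosine algebra of the construction, not
by tuning. Multi-word terms are embedded as the mean of in-vocabulary
tokens; a feature with no in-vocabulary token yields an explicit no-match
marker (`None`) rather than failing the whole table. Matching runs two
passes so that graph relations, computed from the provisional first-pass
assignments, can flip an otherwise tied candidate.

## Knowledge-graph store

An in-memory triple store with the one provenance query shape compiled by
hand rather than a general SPARQL engine; an N-Triples export (rdflib) is
provided for interchange. Triple subjects must resolve to entities;
objects resolve when the id exists and are literals otherwise (the JSON
`[s, p, o]` dialect cannot distinguish the two). Hyperparameters are
stored one triple each as `name=<json value>` so the provenance query
reconstructs the exact name→value map from the graph alone. Entity ids are
case-sensitive opaque strings; labels are matched case-insensitively.
Traversal treats edges as undirected, which is the natural reading for
context expansion. No OWL reasoning, no rule engine, and no network access
anywhere: external terminologies appear only as `external_link` URLs.

## Known limitations

- Exact Shapley is exponential in d; beyond 15 features only the sampled
  estimator is available.
- The interventional value function ignores feature dependence; on
  strongly correlated data it can attribute weight to off-manifold
  coalitions.
- S-LIME's boundary z-test ignores coefficient covariance and tests one
  boundary pair, not the full ranking.
- The synthetic generators use independent features; real-data
  faithfulness numbers will differ.
- No probability calibration is attempted; reported risks are raw model
  probabilities.
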