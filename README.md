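# diaglass

Glass-box diabetes risk prediction for tabular clinical cohorts: train the
standard classifiers, explain their predictions from first principles, and
measure whether those explanations can be trusted.

Machine-learning diabetes predictors are routinely accurate but opaque, and
clinicians reasonably hesitate to act on a risk score they cannot
interrogate. `diaglass` packages the full explanation workflow around such a
predictor:

- **Knowledge graph** (`diaglass.kg`) — a local triple store with per-entity
  cards (label, synonyms, definition, external terminology link). Trained
  models are registered into the graph with `usesAlgorithm` / `trainedOn` /
  `hasHyperparameter` triples, so *"which algorithm and data set produced
  this model?"* is answered by a provenance query.
- **Entity matching** (`diaglass.matching`) — links data-set feature names
  to graph entities with word-embedding cosine similarity, context
  centroids, and a graph-relation bonus, with two-pass disambiguation.
- **Preprocessing** (`diaglass.preprocessing`) — z-score scaling
  (population sd), SMOTE minority oversampling, and Tomek-link cleaning, in
  that fixed order.
- **Models** (`diaglass.models`) — entropy decision tree, bagged random
  forest, and a small feed-forward network (hidden sizes 16 and 8, sigmoid
  activations, softmax output) trained by mini-batch gradient descent. All
  emit class probabilities and standard metrics (accuracy, macro
  precision/recall/F1, ROC/AUC, PR curve).
- **Attribution** (`diaglass.attribution`) — exact and sampled Shapley
  values with an interventional value function, LIME (proximity-weighted
  ridge surrogate solved in closed form), and an S-LIME-style procedure
  that picks the perturbation count by a CLT z-test on the top-k ranking
  boundary.
- **Faithfulness** (`diaglass.faithfulness`) — monotonicity (Spearman ρ
  between |attribution| and expected importances) and implementation
  invariance (mean top-k Jaccard across seeded retrainings).
- **Synthetic cohorts** (`diaglass.datasets`) — generators emulating the
  two standard diabetes benchmarks (8 continuous features, n=768, ~35%
  positive; 14 binary symptoms + age/sex, n=520 with a 200/320 split) with
  *planted* logistic effect sizes, so ground-truth importances are known
  and the faithfulness metrics can be validated end to end.

The Shapley value of feature *j* uses the interventional coalition value

    v(S) = E_b [ f(x_S, b_{F\S}) ]        (background sample b)
    φ_j  = Σ_{S ⊆ F\{j}}  |S|! (d−|S|−1)! / d!  · ( v(S ∪ {j}) − v(S) )

and the LIME surrogate minimizes Σ_i π(z_i) (f(z_i) − β₀ − βᵀz_i)² + λ‖β‖²
with kernel π(z) = exp(−D(x,z)²/σ²) in scaled feature space.

## Worked example

```
$ diaglass simulate cohort --kind earlystage --out cohort.csv
wrote 520 rows x 16 features to cohort.csv
$ diaglass simulate kg --out kg.json
wrote 30 entities, 66 triples to kg.json
$ diaglass simulate embeddings --out vecs.txt
wrote 48 vectors of dim 32 to vecs.txt
$ diaglass train --algo rf --data cohort.csv --no-rebalance --out rf.pkl
{
  "accuracy": 0.9326923076923077,
  "precision": 0.9307692307692308,
  "recall": 0.9265625,
  "f1": 0.9285644195859091,
  "auc": 0.980859375
}
$ diaglass explain --model rf.pkl --data cohort.csv --row 0 --method lime \
      --k 3 --kg kg.json --embeddings vecs.txt
{
  "row": 0,
  "method": "lime",
  "risk_probability": 0.98,
  ...
  "top_k": ["polyuria", "polydipsia", "partial_paresis"],
  "entity_cards": {
    "polyuria": {
      "entity_id": "polyuria",
      "definition": "Production of abnormally large volumes of dilute urine; ...",
      "external_link": "https://example.org/medkb/polyuria"
    },
    ...
  }
}
```

The trained forest separates the held-out fifth of the cohort with ~93%
accuracy; the local explanation of row 0 ranks polyuria and polydipsia as
the dominant symptoms driving its 98% predicted risk — the two largest
planted effects — and attaches each top feature's knowledge-graph card so a
non-specialist can read what the feature means and follow the external
link.

`diaglass faithfulness --data cohort.csv --kind earlystage --algo rf
--method lime` prints the corresponding quality row (monotonicity against
the planted importances and top-k Jaccard across retrainings).

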