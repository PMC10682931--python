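"""Entity matching: link data-set feature names to knowledge-graph entities.

A feature name rarely equals an entity label verbatim ("Genital thrush" vs
"genital_thrush", "frequent urination" vs "polyuria"), and a single name may
have several plausible candidates.  Matching therefore combines three
evidence sources, each a cosine similarity rescaled from [-1, 1] to [0, 1]:

* label similarity — embedding of the feature name vs the entity label (max
  over label and synonyms);
* context similarity — centroid of the other feature names vs the entity
  label, so candidates from the right domain neighbourhood are preferred;
* relation bonus — the fraction of already-matched context entities that
  sit within two undirected hops of the candidate in the graph.

The combined score is ``alpha*label + beta*context + gamma*relation`` with
nonnegative weights summing to 1 (default 0.6/0.3/0.1: label similarity is
the dominant signal).  Table matching runs two passes: pass 1 without the
relation bonus, pass 2 re-scoring with the bonus computed from the pass-1
assignments — graph structure can thus flip an ambiguous assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingIndex, OutOfVocabularyError, cosine, embed_term
from .kg import KnowledgeGraph

DEFAULT_WEIGHTS = (0.6, 0.3, 0.1)


class MatchError(Exception):
    pass


@dataclass
class MatchCandidate:
    """One scored candidate entity for a feature name."""

    entity_id: str
    score: float
    label_sim: float
    context_sim: float
    relation_bonus: float


def _check_weights(weights) -> tuple[float, float, float]:
    a, b, g = (float(w) for w in weights)
    if min(a, b, g) < 0 or abs(a + b + g - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return a, b, g


def _rescale(c: float) -> float:
    """Affine map of a cosine from [-1, 1] to [0, 1]."""
    return (c + 1.0) / 2.0


def _context_centroid(context, index: EmbeddingIndex) -> np.ndarray | None:
    vecs = []
    for term in context:
        try:
            vecs.append(embed_term(index, term))
        except OutOfVocabularyError:
            continue
    if not vecs:
        return None
    return np.mean(vecs, axis=0)


def match_feature(
    feature_name: str,
    context: list[str],
    kg: KnowledgeGraph,
    index: EmbeddingIndex,
    weights=DEFAULT_WEIGHTS,
    matched_context: dict[str, str] | None = None,
) -> list[MatchCandidate]:
    """Rank KG entities as candidates for one feature name.

    ``matched_context`` maps context feature names to their (provisional)
    entity ids; when absent the relation bonus is zero for every candidate.
    Candidates are sorted by score descending, ties broken by
    lexicographically smaller entity id.
    """
    alpha, beta, gamma = _check_weights(weights)
    fvec = embed_term(index, feature_name)  # propagates OOV error
    centroid = _context_centroid([c for c in context if c != feature_name], index)

    context_ids = set((matched_context or {}).values()) - {None}
    candidates = []
    for entity_id, card in kg.entities.items():
        texts = [card.label] + list(card.synonyms)
        sims = []
        for text in texts:
            try:
                sims.append(cosine(fvec, embed_term(index, text)))
            except OutOfVocabularyError:
                continue
        if not sims:
            continue  # entity not embeddable: not a candidate
        label_sim = _rescale(max(sims))
        if centroid is not None:
            try:
                context_sim = _rescale(cosine(centroid, embed_term(index, card.label)))
            except OutOfVocabularyError:
                context_sim = 0.0
        else:
            context_sim = 0.0
        if context_ids:
            near = kg.neighbors(entity_id, depth=2)
            bonus = len(context_ids & near) / len(context_ids)
        else:
            bonus = 0.0
        score = alpha * label_sim + beta * context_sim + gamma * bonus
        candidates.append(
            MatchCandidate(entity_id, score, label_sim, context_sim, bonus)
        )
    if not candidates:
        raise MatchError("no embeddable candidate entity in the graph")
    candidates.sort(key=lambda c: (-c.score, c.entity_id))
    return candidates


def match_table(
    features: list[str],
    kg: KnowledgeGraph,
    index: EmbeddingIndex,
    weights=DEFAULT_WEIGHTS,
) -> dict[str, MatchCandidate | None]:
    """Match every feature of a table; two-pass with relation-bonus rescoring.

    Pass 1 scores on label and context similarity alone; pass 2 recomputes
    every feature's candidates with the relation bonus derived from the
    pass-1 assignments.  A feature whose name is entirely out of vocabulary
    maps to ``None`` (the explicit no-match marker) instead of being dropped.
    """
    _check_weights(weights)

    def best(feature, matched):
        try:
            ranked = match_feature(
                feature, features, kg, index, weights, matched_context=matched
            )
        except (OutOfVocabularyError, MatchError):
            return None
        return ranked[0]

    pass1 = {f: best(f, None) for f in features}
    assignments = {
        f: cand.entity_id for f, cand in pass1.items() if cand is not None
    }
    result: dict[str, MatchCandidate | None] = {}
    for f in features:
        others = {k: v for k, v in assignments.items() if k != f}
        result[f] = best(f, others) if others else pass1[f]
    return result
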