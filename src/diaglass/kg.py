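"""A lightweight local knowledge graph for diabetes concepts and model provenance.

Entities carry human-readable cards (label, synonyms, definition, link to an
external terminology source) and are connected by directed labelled triples.
Trained classifiers are registered into the same graph as model entities with
``usesAlgorithm`` / ``trainedOn`` / ``hasHyperparameter`` triples, so the
question "what algorithm and data set produced this model?" is answered by a
graph query rather than by consulting the training code.

The store is an in-memory triple store with the one provenance query shape
compiled by hand; an optional N-Triples export (via rdflib) is provided for
interchange with standard RDF tooling.  External knowledge sources (UMLS,
SNOMED CT, Wikidata) appear only as ``external_link`` URLs on entity cards;
nothing here touches the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections import deque

ENTITY_TYPES = frozenset(
    {
        "symptom",
        "examination",
        "demographic",
        "risk_factor",
        "complication",
        "drug",
        "dataset",
        "algorithm",
        "model",
    }
)

ALGORITHM_NAMES = frozenset({"decision_tree", "random_forest", "dnn"})


class KGError(Exception):
    """Base class for knowledge-graph errors."""


class NotFoundError(KGError):
    pass


class DanglingReferenceError(KGError):
    pass


class DuplicateIdError(KGError):
    pass


class ParseError(KGError):
    pass


@dataclass
class EntityCard:
    entity_id: str
    label: str
    entity_type: str
    synonyms: list[str] = field(default_factory=list)
    definition: str = ""
    external_link: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be non-empty")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity_type {self.entity_type!r}")


@dataclass(frozen=True)
class Triple:
    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if not self.predicate:
            raise ValueError("predicate must be non-empty")


@dataclass
class TrainedModelCard:
    """Metadata for one trained classifier: the provenance record."""

    model_id: str
    algorithm_name: str
    dataset_ref: str
    seed: int
    hyperparameters: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm_name not in ALGORITHM_NAMES:
            raise ValueError(f"unknown algorithm {self.algorithm_name!r}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModelCard":
        return cls(**json.loads(text))


class KnowledgeGraph:
    """Entity cards plus a set of directed labelled triples.

    Triple objects resolve to entities when the id exists in the graph and
    are treated as literals otherwise; subjects must always resolve.
    """

    def __init__(self) -> None:
        self._entities: dict[str, EntityCard] = {}
        self._triples: set[Triple] = set()

    # -- entities ---------------------------------------------------------
    @property
    def entities(self) -> dict[str, EntityCard]:
        return self._entities

    @property
    def triples(self) -> set[Triple]:
        return self._triples

    def __len__(self) -> int:
        return len(self._entities)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._entities

    def add_entity(self, card: EntityCard) -> None:
        if card.entity_id in self._entities:
            raise DuplicateIdError(f"entity {card.entity_id!r} already exists")
        self._entities[card.entity_id] = card

    def add_triple(self, subject: str, predicate: str, object: str) -> None:
        if subject not in self._entities:
            raise DanglingReferenceError(
                f"triple subject {subject!r} does not resolve to an entity"
            )
        self._triples.add(Triple(subject, predicate, str(object)))

    def lookup_entity(self, entity_id: str) -> EntityCard:
        try:
            return self._entities[entity_id]
        except KeyError:
            raise NotFoundError(f"entity {entity_id!r} not found") from None

    def find_by_label(self, label: str) -> EntityCard | None:
        """Case-insensitive label lookup (ids are case-sensitive, labels not)."""
        needle = label.lower()
        for card in self._entities.values():
            if card.label.lower() == needle:
                return card
        return None

    # -- model provenance -------------------------------------------------
    def register_model(self, card: TrainedModelCard) -> str:
        """Insert a trained-model entity plus its provenance triples.

        Adds ``model --usesAlgorithm--> algorithm``,
        ``model --trainedOn--> dataset`` and one ``hasHyperparameter``
        triple per hyperparameter (object ``"name=<json value>"`` so the
        exact map is reconstructible from the graph).
        """
        if card.dataset_ref not in self._entities:
            raise DanglingReferenceError(
                f"dataset_ref {card.dataset_ref!r} does not resolve"
            )
        if card.model_id in self._entities:
            raise DuplicateIdError(f"model {card.model_id!r} already registered")
        if card.algorithm_name not in self._entities:
            self.add_entity(
                EntityCard(
                    entity_id=card.algorithm_name,
                    label=card.algorithm_name.replace("_", " "),
                    entity_type="algorithm",
                )
            )
        self.add_entity(
            EntityCard(
                entity_id=card.model_id,
                label=card.model_id,
                entity_type="model",
                definition=f"Trained {card.algorithm_name} instance (seed {card.seed})",
            )
        )
        self.add_triple(card.model_id, "usesAlgorithm", card.algorithm_name)
        self.add_triple(card.model_id, "trainedOn", card.dataset_ref)
        self.add_triple(card.model_id, "hasSeed", json.dumps(card.seed))
        for name, value in card.hyperparameters.items():
            self.add_triple(
                card.model_id, "hasHyperparameter", f"{name}={json.dumps(value)}"
            )
        return card.model_id

    def query_provenance(self, model_id: str) -> tuple[str, EntityCard, dict]:
        """Answer "what algorithm and data set trained this model?".

        Returns ``(algorithm_name, dataset EntityCard, hyperparameters)``
        reconstructed purely from the triples written at registration.
        """
        card = self.lookup_entity(model_id)
        if card.entity_type != "model":
            raise NotFoundError(f"{model_id!r} is not a registered model")
        algorithm = dataset = None
        hyper: dict = {}
        for t in self._triples:
            if t.subject != model_id:
                continue
            if t.predicate == "usesAlgorithm":
                algorithm = t.object
            elif t.predicate == "trainedOn":
                dataset = t.object
            elif t.predicate == "hasHyperparameter":
                name, _, raw = t.object.partition("=")
                hyper[name] = json.loads(raw)
        if algorithm is None or dataset is None:
            raise NotFoundError(f"no provenance triples for {model_id!r}")
        return algorithm, self.lookup_entity(dataset), hyper

    # -- traversal --------------------------------------------------------
    def neighbors(self, entity_id: str, depth: int = 1) -> set[str]:
        """Entities reachable within ``depth`` undirected hops; excludes the seed."""
        if entity_id not in self._entities:
            raise NotFoundError(f"entity {entity_id!r} not found")
        if depth < 1:
            raise ValueError("depth must be a positive integer")
        adj: dict[str, set[str]] = {}
        for t in self._triples:
            if t.object in self._entities:
                adj.setdefault(t.subject, set()).add(t.object)
                adj.setdefault(t.object, set()).add(t.subject)
        seen = {entity_id}
        frontier = deque([(entity_id, 0)])
        while frontier:
            node, dist = frontier.popleft()
            if dist == depth:
                continue
            for nxt in adj.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append((nxt, dist + 1))
        seen.discard(entity_id)
        return seen


# -- serialization --------------------------------------------------------

def load_kg(path) -> KnowledgeGraph:
    """Load a graph from the JSON triples dialect.

    Top-level keys: ``"entities"`` (list of card objects) and ``"triples"``
    (list of ``[subject, predicate, object]``).
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    kg = KnowledgeGraph()
    for raw in doc.get("entities", []):
        try:
            kg.add_entity(EntityCard(**raw))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad entity record {raw!r}: {exc}") from exc
    bad = [t for t in doc.get("triples", []) if t[0] not in kg.entities]
    if bad:
        raise DanglingReferenceError(
            f"{path}: triples with unknown subjects: {bad}"
        )
    for s, p, o in doc.get("triples", []):
        kg.add_triple(s, p, o)
    return kg


def write_kg(kg: KnowledgeGraph, path) -> None:
    doc = {
        "entities": [dict(card.__dict__) for card in kg.entities.values()],
        "triples": sorted(
            [t.subject, t.predicate, t.object] for t in kg.triples
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def to_ntriples(kg: KnowledgeGraph) -> str:
    """Export to N-Triples for interchange with standard RDF tooling."""
    import rdflib

    g = rdflib.Graph()
    base = "urn:diaglass:"

    def uri(entity_id: str) -> "rdflib.URIRef":
        return rdflib.URIRef(base + entity_id.replace(" ", "_"))

    for card in kg.entities.values():
        g.add((uri(card.entity_id), rdflib.RDFS.label, rdflib.Literal(card.label)))
        g.add(
            (
                uri(card.entity_id),
                rdflib.URIRef(base + "entityType"),
                rdflib.Literal(card.entity_type),
            )
        )
    for t in kg.triples:
        obj = uri(t.object) if t.object in kg.entities else rdflib.Literal(t.object)
        g.add((uri(t.subject), rdflib.URIRef(base + t.predicate), obj))
    return g.serialize(format="nt")
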