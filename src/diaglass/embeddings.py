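"""Term-embedding index: word2vec-text loading, term embedding, cosine.

The index maps lower-cased single tokens to dense vectors.  Multi-word
terms ("genital thrush", "frequent_urination") are tokenized on
whitespace/underscore/hyphen and embedded as the mean of their
in-vocabulary token vectors, the standard bag-of-tokens fallback for
phrase lookup in word-level embedding models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_TOKEN_SPLIT = re.compile(r"[\s_\-]+")


class EmbeddingError(Exception):
    pass


class OutOfVocabularyError(EmbeddingError):
    """Raised when no token of a term is in the index vocabulary."""


@dataclass
class EmbeddingIndex:
    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        for term, vec in list(self.vectors.items()):
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {term!r} has length {vec.shape}, expected {self.dimension}"
                )
            if np.isnan(vec).any():
                raise ValueError(f"vector for {term!r} contains NaN")
            self.vectors[term.lower()] = vec

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.vectors


def tokenize(term: str) -> list[str]:
    return [t.lower() for t in _TOKEN_SPLIT.split(term.strip()) if t]


def embed_term(index: EmbeddingIndex, term: str) -> np.ndarray:
    """Mean vector of the in-vocabulary tokens of ``term``.

    Raises :class:`OutOfVocabularyError` when no token is known.
    """
    if not term or not term.strip():
        raise ValueError("term must be non-empty")
    hits = [index.vectors[t] for t in tokenize(term) if t in index.vectors]
    if not hits:
        raise OutOfVocabularyError(f"no token of {term!r} is in the vocabulary")
    return np.mean(hits, axis=0)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; rejects zero vectors and length mismatch."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def load_word2vec(path) -> EmbeddingIndex:
    """Read the word2vec text format: header "count dim", then "term v1 ... vd"."""
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingError(f"{path}: bad header {header!r}")
        count, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise EmbeddingError(f"{path}: bad line {parts[0]!r}")
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
    if len(vectors) != count:
        raise EmbeddingError(
            f"{path}: header promised {count} terms, found {len(vectors)}"
        )
    return EmbeddingIndex(dimension=dim, vectors=vectors)


def save_word2vec(index: EmbeddingIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(index.vectors)} {index.dimension}\n")
        for term in sorted(index.vectors):
            vals = " ".join(f"{x:.8g}" for x in index.vectors[term])
            fh.write(f"{term} {vals}\n")
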