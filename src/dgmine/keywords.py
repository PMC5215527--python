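"""Disease-independent keyword expansion by word-vector analogy.

Hand-crafted disease keyword lists do not transfer between diseases.  Given
seed pairs of (source disease word, related term) — e.g. ("cancer",
"proliferation") — and word embeddings, terms related to a *new* disease are
predicted by the analogy query

    q = v(source) - v(related term) + v(new disease word)

and ranked by cosine similarity to q.  The reversed direction
``v(related) - v(source) + v(disease)`` is available via ``direction``; both
conventions appear in the analogy literature and differ only by which side of
the pair anchors the offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingTable",
    "SeedPairList",
    "EmbeddingFormatError",
    "load_embeddings",
    "expand_keywords",
]


class EmbeddingFormatError(ValueError):
    """Raised for malformed word2vec text files."""


@dataclass
class EmbeddingTable:
    """Word vectors: a unique vocabulary and a (V, d) float matrix."""

    vocabulary: list[str]
    vectors: np.ndarray
    _index: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocabulary):
            raise EmbeddingFormatError("vectors must be (V, d) with V == len(vocabulary)")
        if self.vectors.shape[1] < 1:
            raise EmbeddingFormatError("embedding dimension must be >= 1")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise EmbeddingFormatError("vocabulary words must be unique")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not in embedding vocabulary") from None


@dataclass
class SeedPairList:
    """(source disease word, related term) pairs seeding the analogy."""

    pairs: list[tuple[str, str]]

    def restrict_to_vocabulary(self, emb: EmbeddingTable) -> "SeedPairList":
        """Drop pairs with out-of-vocabulary words, warning per dropped pair."""
        kept = []
        for src, rel in self.pairs:
            if src in emb and rel in emb:
                kept.append((src, rel))
            else:
                warnings.warn(
                    f"seed pair ({src!r}, {rel!r}) dropped: word not in vocabulary",
                    stacklevel=2,
                )
        return SeedPairList(kept)


def load_embeddings(path) -> EmbeddingTable:
    """Read word2vec text format: header ``V d`` then one word + d floats per line."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError("header must be 'V d'")
        try:
            n_words, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise EmbeddingFormatError(f"non-integer header: {exc}") from exc
        words: list[str] = []
        seen: set[str] = set()
        rows = np.empty((n_words, dim), dtype=float)
        for i in range(n_words):
            parts = fh.readline().split()
            if len(parts) != dim + 1:
                raise EmbeddingFormatError(
                    f"line {i + 2}: expected word + {dim} floats, got {len(parts)} fields"
                )
            word = parts[0]
            if word in seen:
                raise EmbeddingFormatError(f"duplicate word {word!r}")
            seen.add(word)
            words.append(word)
            rows[i] = [float(x) for x in parts[1:]]
    return EmbeddingTable(words, rows)


def write_embeddings(emb: EmbeddingTable, path) -> None:
    """Write word2vec text format (inverse of :func:`load_embeddings`)."""
    with open(path, "w", encoding="utf-8") as fh:
        v, d = emb.vectors.shape
        fh.write(f"{v} {d}\n")
        for w, row in zip(emb.vocabulary, emb.vectors):
            fh.write(w + " " + " ".join(repr(float(x)) for x in row) + "\n")


def _cosine_to_query(q: np.ndarray, mat: np.ndarray) -> np.ndarray:
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(mat, axis=1)
    denom = qn * norms
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = mat @ q / denom
    sims[~np.isfinite(sims)] = 0.0  # zero-norm vectors score 0
    return sims


def expand_keywords(
    emb: EmbeddingTable,
    seeds: SeedPairList,
    disease_word: str,
    k: int = 20,
    direction: str = "printed",
) -> list[tuple[str, float]]:
    """Predict disease-related terms by analogy over the seed pairs.

    For each seed pair the query point is formed (see module docstring), the
    vocabulary is ranked by cosine similarity to it excluding the three query
    words, and the top ``k`` terms are kept.  Candidates from different seed
    pairs merge by their maximum score; the result is unique terms sorted by
    score descending (ties broken lexicographically).

    Parameters
    ----------
    direction:
        ``"printed"`` uses q = v(source) - v(related) + v(disease);
        ``"reversed"`` uses q = v(related) - v(source) + v(disease).
    """
    if disease_word not in emb:
        raise KeyError(f"disease word {disease_word!r} not in embedding vocabulary")
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("printed", "reversed"):
        raise ValueError("direction must be 'printed' or 'reversed'")
    seeds = seeds.restrict_to_vocabulary(emb)
    best: dict[str, float] = {}
    vocab = np.asarray(emb.vocabulary)
    for src, rel in seeds.pairs:
        if direction == "printed":
            q = emb.vector(src) - emb.vector(rel) + emb.vector(disease_word)
        else:
            q = emb.vector(rel) - emb.vector(src) + emb.vector(disease_word)
        sims = _cosine_to_query(q, emb.vectors)
        excluded = {src, rel, disease_word}
        order = np.argsort(-sims, kind="stable")
        taken = 0
        for idx in order:
            w = str(vocab[idx])
            if w in excluded:
                continue
            s = float(sims[idx])
            if w not in best or s > best[w]:
                best[w] = s
            taken += 1
            if taken >= k:
                break
    return sorted(best.items(), key=lambda t: (-t[1], t[0]))
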