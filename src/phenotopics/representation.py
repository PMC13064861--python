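"""Per-topic keyword and representative-sentence extraction.

Three keyword views are produced for each topic:

* class-based TF-IDF (c-TF-IDF): ``tf(t, c) * log(1 + A / f_t)`` where
  ``tf(t, c)`` is the term frequency in topic class ``c``, ``f_t`` the term's
  total frequency across classes, and ``A`` the average token count per class;
* an embedding re-ranking of the c-TF-IDF candidates by cosine similarity of
  the bare term's embedding to the topic centroid;
* a maximal-marginal-relevance (MMR) selection trading that relevance against
  redundancy with already-selected keywords.

Representative sentences are the topic members closest (cosine) to the topic
centroid.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .corpus_io import Corpus
from .embeddings import EmbeddingBackend, EmbeddingMatrix
from .topic_model import TopicAssignment, topic_centroids

logger = logging.getLogger(__name__)

_TOKEN = re.compile(r"[^\W\d_]+", re.UNICODE)

DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)


def tokenize(text: str) -> list[str]:
    """Lowercased unigram word tokens (alphabetic)."""
    return _TOKEN.findall(text.lower())


@dataclass
class ClassTermMatrix:
    """Term counts aggregated per topic class (outliers excluded)."""

    counts: np.ndarray  # (K, V) int
    vocabulary: list[str]
    topic_ids: list[int]

    @property
    def average_tokens_per_class(self) -> float:
        return float(self.counts.sum() / self.counts.shape[0])

    def term_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.vocabulary)}


@dataclass
class TopicRepresentation:
    topic_id: int
    keywords_ctfidf: list[tuple[str, float]] = field(default_factory=list)
    keywords_embed: list[tuple[str, float]] = field(default_factory=list)
    keywords_mmr: list[tuple[str, float]] = field(default_factory=list)
    representatives: list[str] = field(default_factory=list)  # sentence_ids
    representative_texts: list[str] = field(default_factory=list)


def build_class_term_matrix(
    corpus: Corpus,
    assignment: TopicAssignment,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> ClassTermMatrix:
    """Aggregate token counts over each non-outlier topic's sentences."""
    if assignment.labels.shape[0] != corpus.n_sentences:
        raise ValueError("assignment is not aligned with corpus")
    vocab: dict[str, int] = {}
    per_topic: list[dict[int, int]] = [dict() for _ in range(assignment.K)]
    for label, sentence in zip(assignment.labels, corpus.sentences):
        if label < 0:
            continue
        bucket = per_topic[label]
        for tok in tokenize(sentence.text):
            if tok in stopwords:
                continue
            j = vocab.setdefault(tok, len(vocab))
            bucket[j] = bucket.get(j, 0) + 1
    if not vocab:
        raise ValueError("empty vocabulary after stopword removal")
    counts = np.zeros((assignment.K, len(vocab)), dtype=np.int64)
    for k, bucket in enumerate(per_topic):
        for j, c in bucket.items():
            counts[k, j] = c
    return ClassTermMatrix(
        counts=counts,
        vocabulary=list(vocab),
        topic_ids=list(range(assignment.K)),
    )


def ctfidf(matrix: ClassTermMatrix) -> np.ndarray:
    """Class-based TF-IDF weights: ``tf(t, c) * log(1 + A / f_t)``."""
    tf = matrix.counts.astype(np.float64)
    f_t = tf.sum(axis=0)  # total term frequency across classes
    A = matrix.average_tokens_per_class
    with np.errstate(divide="ignore", invalid="ignore"):
        idf = np.log1p(np.where(f_t > 0, A / f_t, 0.0))
    return tf * idf[None, :]


def top_keywords(
    weights: np.ndarray, matrix: ClassTermMatrix, topic_id: int, n: int = 10
) -> list[tuple[str, float]]:
    """The n highest-weight terms of one topic, ties broken lexicographically,
    restricted to terms actually occurring in the topic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    present = np.flatnonzero(matrix.counts[topic_id] > 0)
    if n > present.size:
        logger.warning("requested %d keywords but topic %d has %d terms", n, topic_id, present.size)
        n = present.size
    scored = sorted(
        ((matrix.vocabulary[j], float(weights[topic_id, j])) for j in present),
        key=lambda tw: (-tw[1], tw[0]),
    )
    return scored[:n]


def embed_rank_keywords(
    candidates: Sequence[str],
    topic_centroid: np.ndarray,
    backend: EmbeddingBackend,
    n: int = 10,
) -> list[tuple[str, float]]:
    """Re-rank candidate terms by cosine of term embedding to topic centroid."""
    if not candidates:
        return []
    vecs = np.asarray(backend.embed(list(candidates)), dtype=float)
    c = np.asarray(topic_centroid, dtype=float)
    c = c / np.linalg.norm(c)
    v = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    sims = v @ c
    order = sorted(range(len(candidates)), key=lambda i: (-sims[i], candidates[i]))
    return [(candidates[i], float(sims[i])) for i in order[:n]]


def mmr_select(
    candidates: Sequence[str],
    candidate_vectors: np.ndarray,
    query: np.ndarray,
    lam: float = 0.5,
    n: int = 10,
) -> list[tuple[str, float]]:
    """Greedy MMR: maximize ``lam*cos(term, query) - (1-lam)*max cos(term,
    selected)``; the first pick is the most query-relevant term."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if n > len(candidates):
        raise ValueError("n exceeds the number of candidates")
    V = np.asarray(candidate_vectors, dtype=float)
    V = V / np.linalg.norm(V, axis=1, keepdims=True)
    q = np.asarray(query, dtype=float)
    q = q / np.linalg.norm(q)
    relevance = V @ q
    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(len(candidates)))
    while len(selected) < n:
        if not selected:
            mmr = relevance[remaining]
        else:
            redundancy = (V[remaining] @ V[selected].T).max(axis=1)
            mmr = lam * relevance[remaining] - (1.0 - lam) * redundancy
        # ties: prefer higher relevance, then lexicographic term
        best = min(
            range(len(remaining)),
            key=lambda i: (-mmr[i], -relevance[remaining[i]], candidates[remaining[i]]),
        )
        selected.append(remaining[best])
        scores.append(float(mmr[best]))
        remaining.pop(best)
    return [(candidates[i], s) for i, s in zip(selected, scores)]


def representative_sentences(
    corpus: Corpus,
    assignment: TopicAssignment,
    embeddings: EmbeddingMatrix,
    topic_id: int,
    n: int = 3,
) -> list[str]:
    """Sentence ids of the n topic members closest to the topic centroid."""
    idx = assignment.topic_indices(topic_id)
    if idx.size == 0:
        raise ValueError(f"topic {topic_id} is empty")
    vecs = embeddings.vectors[idx]
    centroid = vecs.mean(axis=0)
    c = centroid / np.linalg.norm(centroid)
    v = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    sims = v @ c
    order = np.argsort(-sims, kind="stable")[: min(n, idx.size)]
    ids = corpus.sentence_ids()
    return [ids[idx[i]] for i in order]


def represent_topics(
    corpus: Corpus,
    assignment: TopicAssignment,
    embeddings: EmbeddingMatrix,
    backend: EmbeddingBackend,
    n_keywords: int = 10,
    candidate_pool: int = 30,
    mmr_lambda: float = 0.5,
    n_representatives: int = 3,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> list[TopicRepresentation]:
    """Full per-topic representation: three keyword lists + representatives."""
    matrix = build_class_term_matrix(corpus, assignment, stopwords)
    weights = ctfidf(matrix)
    centroids = topic_centroids(assignment, embeddings)
    id_to_text = {s.sentence_id: s.text for s in corpus.sentences}
    reps = []
    for k in range(assignment.K):
        kw = top_keywords(weights, matrix, k, max(candidate_pool, n_keywords))
        candidates = [t for t, _ in kw]
        embed_kw = embed_rank_keywords(candidates, centroids[k], backend, n_keywords)
        cand_vecs = np.asarray(backend.embed(candidates), dtype=float)
        mmr_kw = mmr_select(
            candidates, cand_vecs, centroids[k], mmr_lambda, min(n_keywords, len(candidates))
        )
        rep_ids = representative_sentences(
            corpus, assignment, embeddings, k, n_representatives
        )
        reps.append(
            TopicRepresentation(
                topic_id=k,
                keywords_ctfidf=kw[:n_keywords],
                keywords_embed=embed_kw,
                keywords_mmr=mmr_kw,
                representatives=rep_ids,
                representative_texts=[id_to_text[i] for i in rep_ids],
            )
        )
    return reps


def save_representations(reps: Sequence[TopicRepresentation], path: str | Path) -> None:
    payload = [
        {
            "topic_id": r.topic_id,
            "keywords_ctfidf": r.keywords_ctfidf,
            "keywords_embed": r.keywords_embed,
            "keywords_mmr": r.keywords_mmr,
            "representatives": r.representatives,
            "representative_texts": r.representative_texts,
        }
        for r in reps
    ]
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
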