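"""Synthetic corpora and embedding clouds with known (planted) topic structure.

Two generators with a shared specification:

* :func:`sample_embeddings` — K Gaussian clusters on the unit sphere with a
  controllable centre separation (in units of within-cluster spread) plus a
  fraction of uniformly distributed outliers labelled -1.  Exercises the
  geometric stages (reduction, clustering, stability, comparison).
* :func:`sample_corpus` — short multi-sentence reports whose sentences draw
  content words from per-topic disjoint vocabularies mixed with a shared
  stopword pool.  Report shape mirrors the study structure the package
  targets: a mean of roughly 25 words per report, 1-10 sentences per report,
  unequal topic sizes, and ~9% outlier sentences that mix vocabulary from all
  topics.  The vocabulary is abstract tokens — no attempt is made to imitate
  real phenomenological language.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import RawReport
from .embeddings import EmbeddingMatrix


def _alpha(i: int) -> str:
    """Non-negative int -> lowercase letters (0 -> 'a', 27 -> 'ab')."""
    out = []
    while True:
        out.append(chr(ord("a") + i % 26))
        i //= 26
        if i == 0:
            return "".join(reversed(out))


def _default_vocab(K: int, words_per_topic: int = 14) -> list[list[str]]:
    # purely alphabetic tokens so any word tokenizer keeps them whole
    return [
        [f"top{_alpha(k)}{_alpha(j)}" for j in range(words_per_topic)]
        for k in range(K)
    ]


#: shared function-word pool, mixed into sentences of every topic
DEFAULT_STOPWORD_POOL = [f"fill{_alpha(j)}" for j in range(12)]


@dataclass
class SyntheticSpec:
    """Ground-truth structure of a generated dataset.

    ``sizes`` are per-topic sentence counts (unequal by default, mirroring
    the long-tailed topic-size distribution of real report corpora);
    ``separation`` is the minimum distance between cluster centres in units
    of the within-cluster spread; ``outlier_frac`` adds unassigned points.
    """

    K: int = 5
    sizes: tuple[int, ...] = (200, 120, 90, 60, 40)
    d: int = 64
    separation: float = 8.0
    outlier_frac: float = 0.09
    vocab: list[list[str]] = field(default_factory=list)
    stopword_pool: list[str] = field(default_factory=lambda: list(DEFAULT_STOPWORD_POOL))
    words_per_sentence: tuple[int, int] = (6, 14)
    sentences_per_report: tuple[int, int] = (1, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sizes) != self.K:
            raise ValueError("sizes must have one entry per topic")
        if sum(self.sizes) <= 0:
            raise ValueError("sizes must sum to a positive count")
        if not 0.0 <= self.outlier_frac < 1.0:
            raise ValueError("outlier_frac must lie in [0, 1)")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if not self.vocab:
            self.vocab = _default_vocab(self.K)
        if len(self.vocab) != self.K:
            raise ValueError("vocab must have one word list per topic")
        if any(not v for v in self.vocab):
            raise ValueError("empty topic vocabulary")


def sample_embeddings(spec: SyntheticSpec) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Draw the planted embedding cloud.

    Cluster centres are random orthonormalized directions (pairwise distance
    sqrt(2) on the sphere); the within-cluster Gaussian spread is scaled so
    centre separation is at least ``spec.separation`` spreads.  Points are
    re-normalized onto the unit sphere; outliers are uniform on the sphere.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.K > spec.d:
        raise ValueError("need d >= K for orthogonal centres")
    # orthonormal random centres via QR
    M = rng.standard_normal((spec.d, spec.K))
    Q, _ = np.linalg.qr(M)
    centres = Q.T  # (K, d), pairwise Euclidean distance sqrt(2)
    sigma = np.sqrt(2.0) / spec.separation
    points = []
    labels = []
    for k, size in enumerate(spec.sizes):
        X = centres[k] + sigma * rng.standard_normal((size, spec.d))
        points.append(X)
        labels.extend([k] * size)
    n_inliers = sum(spec.sizes)
    n_out = round(spec.outlier_frac / (1.0 - spec.outlier_frac) * n_inliers)
    if n_out:
        O = rng.standard_normal((n_out, spec.d))
        points.append(O)
        labels.extend([-1] * n_out)
    X = np.vstack(points)
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    labels = np.asarray(labels, dtype=int)
    order = rng.permutation(X.shape[0])
    X, labels = X[order], labels[order]
    matrix = EmbeddingMatrix(
        vectors=X, row_index=[f"syn:{i}" for i in range(X.shape[0])], unit_norm=True
    )
    return matrix, labels


def sample_corpus(spec: SyntheticSpec) -> tuple[list[RawReport], dict[str, int]]:
    """Draw reports with ground-truth sentence topics.

    Returns the report list and a map ``sentence text -> true topic`` (-1 for
    outlier sentences, which mix all topic vocabularies).  Sentences within a
    report share a topic with high probability, echoing how one reflection
    tends to dwell on related facets.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sizes = list(spec.sizes)
    n_inliers = sum(sizes)
    n_out = round(spec.outlier_frac / (1.0 - spec.outlier_frac) * n_inliers)
    # pool of (topic, sentence_text) pairs, then packed into reports
    pool: list[tuple[int, str]] = []
    for k, size in enumerate(sizes):
        for _ in range(size):
            pool.append((k, _draw_sentence(rng, spec, k)))
    for _ in range(n_out):
        pool.append((-1, _draw_sentence(rng, spec, -1)))
    rng.shuffle(pool)
    reports: list[RawReport] = []
    truth: dict[str, int] = {}
    i = 0
    rid = 0
    lo, hi = spec.sentences_per_report
    while i < len(pool):
        n_sent = int(rng.integers(lo, hi + 1))
        chunk = pool[i : i + n_sent]
        i += len(chunk)
        text = " ".join(s for _, s in chunk)
        reports.append(RawReport(report_id=f"r{rid}", condition="SYN", text=text))
        for topic, sent in chunk:
            truth[sent] = topic
        rid += 1
    return reports, truth


def _draw_sentence(rng: np.random.Generator, spec: SyntheticSpec, topic: int) -> str:
    lo, hi = spec.words_per_sentence
    n_words = int(rng.integers(lo, hi + 1))
    words = []
    for _ in range(n_words):
        if topic >= 0:
            source = spec.vocab[topic] if rng.random() < 0.85 else spec.stopword_pool
        else:
            # outliers mix every topic's vocabulary plus stopwords
            if rng.random() < 0.5:
                source = spec.stopword_pool
            else:
                source = spec.vocab[int(rng.integers(0, spec.K))]
        words.append(source[int(rng.integers(0, len(source)))])
    return " ".join(words) + "."
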