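"""Topic-quality scoring.

Two complementary coherence metrics:

* **Embedding coherence** ``C_embed``: for topic ``T_k`` with ``N_k`` member
  embeddings, the intra-topic coherence is the mean cosine similarity over
  all ``C(N_k, 2)`` unique pairs,

      C_intra(T_k) = (1 / C(N_k,2)) * sum_{i<j} cos(e_i, e_j),

  and ``C_embed`` is the unweighted mean of ``C_intra`` over the K non-outlier
  topics.  It measures semantic compactness directly in embedding space.

* **Word coherence** ``C_v``: a sliding-window co-occurrence metric.  Boolean
  window counts over the corpus yield NPMI association scores between each
  topic's top words; each word's NPMI context vector (over the top-word set)
  is compared to the others by cosine, the pairwise similarities are averaged
  within the topic, and topics are averaged to one score.  It measures lexical
  interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingMatrix
from .topic_model import TopicAssignment

#: smoothing for log(0) guards in NPMI
NPMI_EPS = 1e-12


@dataclass
class CoherenceScores:
    c_embed: float
    c_v: float
    per_topic_c_intra: np.ndarray


def c_intra(topic_embeddings: np.ndarray) -> float:
    """Mean cosine similarity over all unique pairs of rows (exact, no
    sampling).  Requires at least two rows."""
    X = np.asarray(topic_embeddings, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("c_intra undefined for fewer than 2 embeddings")
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    gram = Xn @ Xn.T
    iu = np.triu_indices(n, k=1)
    return float(gram[iu].mean())


def c_embed(assignment: TopicAssignment, embeddings: EmbeddingMatrix) -> CoherenceScores:
    """Unweighted mean of per-topic ``c_intra``; outlier class excluded.

    Returned as a partial :class:`CoherenceScores` with ``c_v`` unset (nan).
    """
    if assignment.K < 1:
        raise ValueError("no non-outlier topics")
    per_topic = np.empty(assignment.K)
    for k in range(assignment.K):
        idx = assignment.topic_indices(k)
        if idx.size < 2:
            raise ValueError(f"topic {k} has {idx.size} members; need >= 2")
        per_topic[k] = c_intra(embeddings.vectors[idx])
    return CoherenceScores(
        c_embed=float(per_topic.mean()), c_v=float("nan"), per_topic_c_intra=per_topic
    )


def _window_counts(
    docs_tokens: Sequence[Sequence[str]], words: Sequence[str], window: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Boolean sliding-window counts restricted to ``words``.

    Returns (single counts vector, pair count matrix, number of windows).
    A document shorter than the window contributes a single window.
    """
    word_index = {w: i for i, w in enumerate(words)}
    m = len(words)
    singles = np.zeros(m, dtype=np.int64)
    pairs = np.zeros((m, m), dtype=np.int64)
    n_windows = 0
    for tokens in docs_tokens:
        if not tokens:
            continue
        n_win = max(1, len(tokens) - window + 1)
        for start in range(n_win):
            n_windows += 1
            present = sorted(
                {word_index[t] for t in tokens[start : start + window] if t in word_index}
            )
            for a, i in enumerate(present):
                singles[i] += 1
                for j in present[a + 1 :]:
                    pairs[i, j] += 1
                    pairs[j, i] += 1
    return singles, pairs, n_windows


def npmi_matrix(
    singles: np.ndarray, pairs: np.ndarray, n_windows: int, eps: float = NPMI_EPS
) -> np.ndarray:
    """NPMI(i, j) from window counts, with diagonal fixed at 1.

    Perfect co-occurrence (joint probability 1) is defined as NPMI = 1;
    zero counts are guarded by ``eps``.
    """
    if n_windows < 1:
        raise ValueError("no co-occurrence windows")
    m = singles.shape[0]
    P = singles / n_windows
    out = np.empty((m, m))
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            p_ij = pairs[i, j] / n_windows
            if p_ij >= 1.0 - 1e-12:
                v = 1.0
            else:
                p_ij = max(p_ij, eps)
                denom = max(P[i] * P[j], eps)
                v = log(p_ij / denom) / (-log(p_ij))
            out[i, j] = out[j, i] = v
    return out


def c_v(
    topics_top_words: Sequence[Sequence[str]],
    docs_tokens: Sequence[Sequence[str]],
    window: int = 110,
    top_n: int = 10,
    eps: float = NPMI_EPS,
) -> float:
    """Sliding-window NPMI context-vector coherence, averaged over topics.

    ``docs_tokens`` are the tokenized reference documents (sentences, the
    modelling unit).  For each topic only the first ``top_n`` words are used;
    a topic whose words never occur in the corpus raises.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    if not docs_tokens:
        raise ValueError("empty reference corpus")
    topic_scores = []
    for words in topics_top_words:
        words = list(dict.fromkeys(words))[:top_n]
        if len(words) < 2:
            raise ValueError("topic needs >= 2 distinct top words")
        singles, pairs, n_windows = _window_counts(docs_tokens, words, window)
        if singles.sum() == 0:
            raise ValueError(f"no top word of topic {words!r} occurs in the corpus")
        npmi = npmi_matrix(singles, pairs, n_windows, eps)
        # context vector of word i = NPMI row i over the top-word set
        norms = np.linalg.norm(npmi, axis=1)
        sims = []
        m = len(words)
        for i in range(m):
            for j in range(i + 1, m):
                sims.append(float(npmi[i] @ npmi[j] / (norms[i] * norms[j])))
        topic_scores.append(float(np.mean(sims)))
    return float(np.mean(topic_scores))


def score_solution(
    assignment: TopicAssignment,
    embeddings: EmbeddingMatrix,
    topics_top_words: Sequence[Sequence[str]],
    docs_tokens: Sequence[Sequence[str]],
    window: int = 110,
    top_n: int = 10,
) -> CoherenceScores:
    """Both metrics for one topic solution."""
    scores = c_embed(assignment, embeddings)
    scores.c_v = c_v(topics_top_words, docs_tokens, window=window, top_n=top_n)
    return scores
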