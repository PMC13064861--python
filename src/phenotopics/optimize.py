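"""Multi-objective hyperparameter search over the reduce->cluster stack.

Both coherence metrics (C_embed, C_v) are maximized jointly: trials are
collected, the exact Pareto front (non-dominated set) is extracted, and the
final configuration is the front member with the highest C_embed — embedding
coherence is prioritized because it judges the semantic geometry directly,
with C_v breaking ties.

The sampler is a seeded uniform random search over the configured ranges;
degenerate trials (no topics, or a topic too small to score) are recorded as
invalid rather than raising, so the front stays meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .coherence import CoherenceScores, c_embed, c_v
from .corpus_io import Corpus
from .embeddings import EmbeddingMatrix
from .representation import build_class_term_matrix, ctfidf, top_keywords, tokenize
from .topic_model import TopicAssignment, TopicModelConfig, cluster, reduce

logger = logging.getLogger(__name__)


@dataclass
class SearchSpace:
    """Uniform ranges for the five tuned hyperparameters (inclusive bounds)."""

    n_components: tuple[int, int] = (2, 30)
    n_neighbors: tuple[int, int] = (5, 50)
    min_dist: tuple[float, float] = (0.0, 0.5)
    min_cluster_size: tuple[int, int] = (5, 50)
    min_samples: tuple[int, int] | None = None  # None: 1..min_cluster_size
    n_trials: int = 100
    sampler_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for lo, hi in (self.n_components, self.n_neighbors, self.min_cluster_size):
            if lo > hi:
                raise ValueError("empty integer range in search space")
        if self.min_dist[0] > self.min_dist[1]:
            raise ValueError("empty min_dist range")

    def sample(self, rng: np.random.Generator, seed: int) -> TopicModelConfig:
        mcs = int(rng.integers(self.min_cluster_size[0], self.min_cluster_size[1] + 1))
        if self.min_samples is None:
            ms = int(rng.integers(1, mcs + 1))
        else:
            ms = int(rng.integers(self.min_samples[0], self.min_samples[1] + 1))
        return TopicModelConfig(
            n_components=int(rng.integers(self.n_components[0], self.n_components[1] + 1)),
            n_neighbors=int(rng.integers(self.n_neighbors[0], self.n_neighbors[1] + 1)),
            min_dist=float(rng.uniform(self.min_dist[0], self.min_dist[1])),
            min_cluster_size=mcs,
            min_samples=ms,
            seed=seed,
        )


@dataclass
class TrialResult:
    config: TopicModelConfig
    scores: CoherenceScores | None
    n_topics: int
    valid: bool
    note: str = ""

    @property
    def objectives(self) -> tuple[float, float]:
        if not self.valid or self.scores is None:
            raise ValueError("invalid trial carries no objectives")
        return (self.scores.c_embed, self.scores.c_v)


@dataclass
class ParetoFront:
    trials: list[TrialResult] = field(default_factory=list)


def evaluate_config(
    corpus: Corpus,
    embeddings: EmbeddingMatrix,
    config: TopicModelConfig,
    cv_window: int = 110,
    cv_top_n: int = 10,
    assignment: TopicAssignment | None = None,
) -> TrialResult:
    """Run reduce -> cluster -> keyword extraction -> coherence for one
    configuration.  Deterministic given ``config.seed``.

    ``assignment`` short-circuits the fit (used when scoring a precomputed
    solution).  Degenerate outcomes yield ``valid=False``, never an exception.
    """
    n, d = embeddings.vectors.shape
    if assignment is None:
        if (
            config.n_components >= min(n, d)
            or config.n_neighbors >= n
            or config.min_cluster_size > n
        ):
            return TrialResult(config, None, 0, False, "config infeasible for data size")
        reduced = reduce(embeddings, config)
        assignment = cluster(reduced, config)
    if assignment.K == 0:
        return TrialResult(config, None, 0, False, "no clusters found")
    sizes = assignment.topic_sizes()
    if any(sizes.get(k, 0) < 2 for k in range(assignment.K)):
        return TrialResult(config, None, assignment.K, False, "topic with < 2 members")
    try:
        matrix = build_class_term_matrix(corpus, assignment)
        weights = ctfidf(matrix)
        top_words = [
            [t for t, _ in top_keywords(weights, matrix, k, cv_top_n)]
            for k in range(assignment.K)
        ]
        scores = c_embed(assignment, embeddings)
        docs_tokens = [tokenize(t) for t in corpus.texts()]
        scores.c_v = c_v(top_words, docs_tokens, window=cv_window, top_n=cv_top_n)
    except ValueError as exc:
        return TrialResult(config, None, assignment.K, False, f"scoring failed: {exc}")
    return TrialResult(config, scores, assignment.K, True)


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """a dominates b under (>=, >=) with at least one strict inequality."""
    return a[0] >= b[0] and a[1] >= b[1] and (a[0] > b[0] or a[1] > b[1])


def pareto_front(trials: Sequence[TrialResult]) -> ParetoFront:
    """Exact non-dominated subset of the valid trials."""
    valid = [t for t in trials if t.valid]
    if not valid:
        raise ValueError("no valid trials")
    members = [
        t
        for t in valid
        if not any(
            _dominates(other.objectives, t.objectives)
            for other in valid
            if other is not t
        )
    ]
    return ParetoFront(trials=members)


def _config_hash(config: TopicModelConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()


def select_final(front: ParetoFront) -> TrialResult:
    """Front member with maximal C_embed; ties broken by higher C_v, then
    fewer topics, then config hash."""
    if not front.trials:
        raise ValueError("empty Pareto front")
    return min(
        front.trials,
        key=lambda t: (
            -t.scores.c_embed,
            -t.scores.c_v,
            t.n_topics,
            _config_hash(t.config),
        ),
    )


def optimize(
    corpus: Corpus,
    embeddings: EmbeddingMatrix,
    space: SearchSpace,
    cv_window: int = 110,
    cv_top_n: int = 10,
) -> tuple[list[TrialResult], ParetoFront, TrialResult]:
    """Run ``space.n_trials`` seeded random-search evaluations and return the
    full audit trail, the Pareto front, and the selected configuration."""
    rng = np.random.default_rng(space.sampler_seed)
    trials: list[TrialResult] = []
    for i in range(space.n_trials):
        config = space.sample(rng, seed=int(rng.integers(0, 2**31 - 1)))
        trial = evaluate_config(corpus, embeddings, config, cv_window, cv_top_n)
        trials.append(trial)
        if trial.valid:
            logger.info(
                "trial %d: c_embed=%.4f c_v=%.4f K=%d",
                i, trial.scores.c_embed, trial.scores.c_v, trial.n_topics,
            )
        else:
            logger.info("trial %d invalid: %s", i, trial.note)
    valid = [t for t in trials if t.valid]
    if not valid:
        raise RuntimeError(
            f"all {space.n_trials} trials invalid; notes: "
            + "; ".join(sorted({t.note for t in trials}))
        )
    front = pareto_front(trials)
    return trials, front, select_final(front)


def save_trials(trials: Sequence[TrialResult], path: str | Path) -> None:
    """Study log: one JSON trial per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in trials:
            row = {
                "config": asdict(t.config),
                "valid": t.valid,
                "n_topics": t.n_topics,
                "note": t.note,
            }
            if t.valid:
                row["c_embed"] = t.scores.c_embed
                row["c_v"] = t.scores.c_v
            fh.write(json.dumps(row) + "\n")
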