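"""Topic discovery: UMAP reduction, HDBSCAN density clustering, and optional
outlier reassignment by embedding similarity.

The number of topics is emergent: HDBSCAN labels each sentence with a topic
``0..K-1`` or with ``-1`` for outliers (sentences not confidently assignable
to any dense region).  Outliers can afterwards be reassigned to the topic
whose centroid (mean of original-space unit embeddings) is most cosine-similar,
subject to a threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingMatrix

logger = logging.getLogger(__name__)


@dataclass
class TopicModelConfig:
    """Hyperparameters of the reduce -> cluster stack.

    ``n_components``, ``n_neighbors`` and ``min_dist`` steer UMAP;
    ``min_cluster_size`` and ``min_samples`` steer HDBSCAN granularity and
    noise tolerance.  ``seed`` fixes the UMAP random state.
    """

    n_components: int = 5
    n_neighbors: int = 15
    min_dist: float = 0.0
    min_cluster_size: int = 10
    min_samples: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2 or self.n_neighbors < 2:
            raise ValueError("n_components and n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")
        if self.min_cluster_size < 2 or self.min_samples < 1:
            raise ValueError("min_cluster_size >= 2 and min_samples >= 1 required")
        if self.min_samples > self.min_cluster_size:
            warnings.warn(
                "min_samples > min_cluster_size is unusual and may over-prune",
                stacklevel=2,
            )


@dataclass
class TopicAssignment:
    """Cluster labels over a corpus: values in {-1, 0, .., K-1}."""

    labels: np.ndarray
    K: int
    reduced: np.ndarray | None = None
    config: TopicModelConfig | None = None

    def topic_indices(self, topic: int) -> np.ndarray:
        return np.flatnonzero(self.labels == topic)

    def topic_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(t): int(c) for t, c in zip(ids, counts)}

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == -1))


def reduce(embeddings: EmbeddingMatrix, config: TopicModelConfig) -> np.ndarray:
    """Project the embedding matrix to ``config.n_components`` dimensions with
    UMAP.  Deterministic for a fixed ``config.seed``."""
    n, d = embeddings.vectors.shape
    if config.n_components >= d or config.n_components >= n:
        raise ValueError(
            f"n_components={config.n_components} must be < min(n={n}, d={d})"
        )
    if n <= config.n_neighbors:
        raise ValueError(f"need n > n_neighbors ({n} <= {config.n_neighbors})")
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value .* overridden")
        reducer = umap.UMAP(
            n_components=config.n_components,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            metric="cosine",
            random_state=config.seed,
        )
        return np.asarray(reducer.fit_transform(embeddings.vectors), dtype=np.float64)


def cluster(reduced: np.ndarray, config: TopicModelConfig) -> TopicAssignment:
    """Density-cluster the reduced points.  K is emergent; points in no dense
    region get label -1."""
    reduced = np.asarray(reduced, dtype=np.float64)
    if not np.all(np.isfinite(reduced)):
        raise ValueError("reduced matrix contains non-finite values")
    n = reduced.shape[0]
    if n < config.min_cluster_size:
        logger.warning(
            "n=%d < min_cluster_size=%d: labelling all points as outliers",
            n,
            config.min_cluster_size,
        )
        return TopicAssignment(
            labels=np.full(n, -1, dtype=int), K=0, reduced=reduced, config=config
        )
    from sklearn.cluster import HDBSCAN

    model = HDBSCAN(
        min_cluster_size=config.min_cluster_size,
        min_samples=config.min_samples,
        metric="euclidean",
        # a corpus that is one dense theme is a valid 1-topic solution
        allow_single_cluster=True,
        copy=True,
    )
    labels = np.asarray(model.fit(reduced).labels_, dtype=int)
    K = int(labels.max()) + 1 if np.any(labels >= 0) else 0
    return TopicAssignment(labels=labels, K=K, reduced=reduced, config=config)


def topic_centroids(assignment: TopicAssignment, embeddings: EmbeddingMatrix) -> np.ndarray:
    """K x d matrix of topic centroids: means of original-space embeddings."""
    return np.vstack(
        [
            embeddings.vectors[assignment.topic_indices(k)].mean(axis=0)
            for k in range(assignment.K)
        ]
    )


def reassign_outliers(
    assignment: TopicAssignment,
    embeddings: EmbeddingMatrix,
    threshold: float = 0.0,
) -> TopicAssignment:
    """Relabel each outlier to its most cosine-similar topic centroid when that
    similarity reaches ``threshold``; all non-outlier labels are untouched.

    Centroids live in the original embedding space, not the reduced space.
    """
    if assignment.K == 0:
        logger.warning("no non-outlier topics; reassign_outliers is a no-op")
        return assignment
    labels = assignment.labels.copy()
    out_idx = np.flatnonzero(labels == -1)
    if out_idx.size:
        centroids = topic_centroids(assignment, embeddings)
        c_norm = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
        vecs = embeddings.vectors[out_idx]
        v_norm = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        sims = v_norm @ c_norm.T  # (n_out, K)
        best = np.argmax(sims, axis=1)
        best_sim = sims[np.arange(out_idx.size), best]
        accept = best_sim >= threshold
        labels[out_idx[accept]] = best[accept]
    return TopicAssignment(
        labels=labels, K=assignment.K, reduced=assignment.reduced, config=assignment.config
    )


def fit_topics(
    embeddings: EmbeddingMatrix,
    config: TopicModelConfig,
    reassign: bool = False,
    reassign_threshold: float = 0.0,
) -> TopicAssignment:
    """reduce -> cluster (-> optional outlier reassignment)."""
    reduced = reduce(embeddings, config)
    assignment = cluster(reduced, config)
    if reassign and assignment.K > 0:
        assignment = reassign_outliers(assignment, embeddings, reassign_threshold)
    return assignment


def save_assignment(
    assignment: TopicAssignment, embeddings: EmbeddingMatrix, path: str | Path
) -> None:
    """Persist config, K, labels and original-space centroids as JSON so
    downstream stages can run without refitting."""
    payload = {
        "config": asdict(assignment.config) if assignment.config else None,
        "K": assignment.K,
        "labels": assignment.labels.tolist(),
        "row_index": embeddings.row_index,
        "centroids": topic_centroids(assignment, embeddings).tolist()
        if assignment.K
        else [],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_assignment(path: str | Path) -> tuple[TopicAssignment, np.ndarray, list[str]]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    config = TopicModelConfig(**payload["config"]) if payload["config"] else None
    assignment = TopicAssignment(
        labels=np.asarray(payload["labels"], dtype=int), K=int(payload["K"]), config=config
    )
    return assignment, np.asarray(payload["centroids"], dtype=float), list(payload["row_index"])
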