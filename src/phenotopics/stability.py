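"""Bootstrap stability of a topic solution.

The model is refit on random subsamples (default 80% of the sentences,
drawn without replacement) and each refit's topics are aligned to the
reference solution by cosine similarity of their centroids in the original
embedding space: for every reference topic, the best-matching bootstrap
centroid similarity is recorded.  A high mean best-match similarity means the
same semantic topic centres re-emerge from partial data — topic-level
stability, deliberately not sentence-level reassignment stability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingMatrix
from .topic_model import (
    TopicAssignment,
    TopicModelConfig,
    cluster,
    reduce,
    topic_centroids,
)

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    n_iterations: int
    subsample_frac: float
    per_topic_mean: np.ndarray
    per_topic_sd: np.ndarray
    overall_mean: float
    overall_sd: float
    seed: int
    n_failed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["per_topic_mean"] = self.per_topic_mean.tolist()
        payload["per_topic_sd"] = self.per_topic_sd.tolist()
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def align_topics(
    reference_centroids: np.ndarray, bootstrap_centroids: np.ndarray
) -> np.ndarray:
    """For each reference centroid, the maximum cosine similarity over the
    bootstrap centroids (best match; one-to-many matches allowed)."""
    R = np.asarray(reference_centroids, dtype=float)
    B = np.asarray(bootstrap_centroids, dtype=float)
    if R.ndim != 2 or B.ndim != 2 or R.shape[0] < 1 or B.shape[0] < 1:
        raise ValueError("need at least one centroid on each side")
    Rn = R / np.linalg.norm(R, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    return (Rn @ Bn.T).max(axis=1)


def bootstrap_stability(
    embeddings: EmbeddingMatrix,
    config: TopicModelConfig,
    reference: TopicAssignment | None = None,
    n_iterations: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> StabilityReport:
    """Refit on ``n_iterations`` seeded subsamples and align to the reference.

    The reference solution is fit once with ``config`` unless supplied.  Each
    iteration uses a fresh UMAP seed derived from the master ``seed``.  A
    subsample that yields no clusters is recorded as failed and excluded;
    more than 50% failures raises (the configuration is unstable).
    """
    if not 0.0 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must lie in (0, 1]")
    n = embeddings.n
    n_sub = max(1, round(subsample_frac * n))
    if n_sub < config.min_cluster_size:
        raise ValueError("subsample smaller than min_cluster_size")
    if reference is None:
        reference = cluster(reduce(embeddings, config), config)
    if reference.K == 0:
        raise ValueError("reference solution has no topics")
    ref_centroids = topic_centroids(reference, embeddings)

    rng = np.random.default_rng(seed)
    per_iter_sims: list[np.ndarray] = []
    n_failed = 0
    for _ in range(n_iterations):
        iter_seed = int(rng.integers(0, 2**31 - 1))
        idx = rng.choice(n, size=n_sub, replace=False)
        sub = EmbeddingMatrix(
            vectors=embeddings.vectors[idx],
            row_index=[embeddings.row_index[i] for i in idx],
            unit_norm=embeddings.unit_norm,
        )
        iter_config = TopicModelConfig(**{**asdict(config), "seed": iter_seed})
        try:
            boot = cluster(reduce(sub, iter_config), iter_config)
        except ValueError:
            boot = None
        if boot is None or boot.K == 0:
            n_failed += 1
            continue
        boot_centroids = topic_centroids(boot, sub)
        per_iter_sims.append(align_topics(ref_centroids, boot_centroids))
    if n_failed > n_iterations / 2:
        raise RuntimeError(
            f"{n_failed}/{n_iterations} bootstrap iterations failed; "
            "configuration is unstable"
        )
    sims = np.vstack(per_iter_sims)  # (n_ok, K)
    iter_means = sims.mean(axis=1)
    return StabilityReport(
        n_iterations=n_iterations,
        subsample_frac=subsample_frac,
        per_topic_mean=sims.mean(axis=0),
        per_topic_sd=sims.std(axis=0, ddof=0),
        overall_mean=float(iter_means.mean()),
        overall_sd=float(iter_means.std(ddof=0)),
        seed=seed,
        n_failed=n_failed,
    )
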