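import numpy as np
import pytest

import phenotopics as pt


@pytest.fixture(scope="session")
def mock_backend():
    return pt.hashed_projection_backend(dim=64, seed=7)


def make_blobs(K, size, d=16, spread=0.05, seed=0, outliers=0):
    """K well-separated Gaussian blobs on the unit sphere + uniform outliers.

    Returns (unit-norm matrix, labels) with outliers labelled -1.
    """
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((d, K))
    Q, _ = np.linalg.qr(M)
    centres = Q.T
    X = np.repeat(centres, size, axis=0) + spread * rng.standard_normal((K * size, d))
    labels = np.repeat(np.arange(K), size)
    if outliers:
        X = np.vstack([X, rng.standard_normal((outliers, d))])
        labels = np.concatenate([labels, -np.ones(outliers, dtype=int)])
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    matrix = pt.EmbeddingMatrix(
        vectors=X, row_index=[f"s{i}" for i in range(X.shape[0])], unit_norm=True
    )
    return matrix, labels


@pytest.fixture(scope="session")
def synthetic_pipeline():
    """Default synthetic corpus taken through embed -> fit once per session."""
    spec = pt.SyntheticSpec(seed=11)
    reports, truth = pt.sample_corpus(spec)
    corpus = pt.build_corpus(reports)
    backend = pt.hashed_projection_backend(seed=11)
    emb = pt.embed_corpus(corpus, backend)
    assignment = pt.fit_topics(emb, pt.TopicModelConfig(seed=11))
    true_labels = np.array([truth[s.text] for s in corpus.sentences])
    return {
        "spec": spec,
        "corpus": corpus,
        "backend": backend,
        "embeddings": emb,
        "assignment": assignment,
        "true_labels": true_labels,
    }
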