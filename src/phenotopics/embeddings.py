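"""Sentence embeddings behind a pluggable backend, plus cosine primitives.

The production path targets a 1024-dimensional sentence-transformer; that
model is an optional download and nothing in this package requires it.  The
:class:`HashedProjectionBackend` is a deterministic, dependency-free backend
that maps token-hash count vectors through a seeded Gaussian projection: it
preserves lexical overlap (shared-vocabulary sentences land closer than
disjoint-vocabulary ones, in expectation), which is all the pipeline's
geometry needs for testing and simulation.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus_io import Corpus


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Text -> vector contract."""

    name: str
    dim: int
    deterministic: bool

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # (n, dim)
        ...


@dataclass
class EmbeddingMatrix:
    """Row-aligned sentence vectors: row i embeds sentence ``row_index[i]``."""

    vectors: np.ndarray
    row_index: list[str]
    unit_norm: bool = False

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def rows_for(self, mask_or_indices) -> np.ndarray:
        return self.vectors[mask_or_indices]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-zero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def embed_corpus(
    corpus: Corpus, backend: EmbeddingBackend, normalize: bool = True
) -> EmbeddingMatrix:
    """Embed every corpus sentence, preserving corpus order.

    With ``normalize`` the rows are L2-normalized once here, so that cosine
    similarity reduces to a dot product everywhere downstream.
    """
    if corpus.n_sentences == 0:
        raise ValueError("cannot embed an empty corpus")
    vectors = np.asarray(backend.embed(corpus.texts()), dtype=np.float64)
    if vectors.shape != (corpus.n_sentences, backend.dim):
        raise ValueError(
            f"backend {backend.name!r} returned shape {vectors.shape}, "
            f"expected {(corpus.n_sentences, backend.dim)}"
        )
    if normalize:
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("backend produced a zero vector; cannot normalize")
        vectors = vectors / norms
    return EmbeddingMatrix(
        vectors=vectors, row_index=corpus.sentence_ids(), unit_norm=normalize
    )


_TOKEN = re.compile(r"[^\W_]+", re.UNICODE)


def _stable_bucket(token: str, n_buckets: int) -> int:
    digest = hashlib.md5(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % n_buckets


@dataclass
class HashedProjectionBackend:
    """Deterministic bag-of-words embedding: hashed token counts projected by
    a seeded random Gaussian matrix, then L2-normalized."""

    # 256 dims keeps random projections of disjoint vocabularies close to
    # orthogonal; far fewer dimensions risks spurious topic overlap
    dim: int = 256
    seed: int = 0
    n_buckets: int = 4096
    deterministic: bool = True
    name: str = field(init=False)

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        self.name = f"hashed-projection-d{self.dim}-s{self.seed}"
        rng = np.random.default_rng(self.seed)
        self._projection = rng.standard_normal((self.n_buckets, self.dim)) / np.sqrt(
            self.dim
        )

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dim))
        for i, text in enumerate(texts):
            tokens = _TOKEN.findall(text.lower())
            if not tokens:
                raise ValueError(f"cannot embed text without word tokens: {text!r}")
            counts: dict[int, int] = {}
            for tok in tokens:
                b = _stable_bucket(tok, self.n_buckets)
                counts[b] = counts.get(b, 0) + 1
            vec = np.zeros(self.dim)
            for b, c in counts.items():
                vec += c * self._projection[b]
            norm = np.linalg.norm(vec)
            if norm == 0.0:
                raise ValueError(f"degenerate zero embedding for {text!r}")
            out[i] = vec / norm
        return out


def hashed_projection_backend(dim: int = 256, seed: int = 0) -> HashedProjectionBackend:
    return HashedProjectionBackend(dim=dim, seed=seed)


def sentence_transformer_backend(model_name: str = "Qwen/Qwen3-Embedding-0.6B"):
    """Production backend wrapping a sentence-transformer model (1024-d by
    default).  Requires the optional ``sentence-transformers`` dependency and
    a locally available model; raises ImportError otherwise."""
    try:
        from sentence_transformers import SentenceTransformer  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "sentence-transformers is not installed; use "
            "hashed_projection_backend() for an offline deterministic backend"
        ) from exc

    model = SentenceTransformer(model_name)  # pragma: no cover

    class _STBackend:  # pragma: no cover
        name = f"sentence-transformer:{model_name}"
        dim = model.get_sentence_embedding_dimension()
        deterministic = True

        def embed(self, texts):
            return np.asarray(model.encode(list(texts)))

    return _STBackend()  # pragma: no cover


# ---------------------------------------------------------------------------
# Disk cache: .npy matrix + JSON sidecar (row index, dim, normalized flag).

def corpus_hash(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for s in corpus.sentences:
        h.update(s.sentence_id.encode())
        h.update(b"\x00")
        h.update(s.text.encode())
        h.update(b"\x01")
    return h.hexdigest()[:16]


def save_embeddings(matrix: EmbeddingMatrix, path: str | Path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), matrix.vectors)
    sidecar = {
        "row_index": matrix.row_index,
        "dim": matrix.dim,
        "unit_norm": matrix.unit_norm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_embeddings(path: str | Path) -> EmbeddingMatrix:
    path = Path(path)
    vectors = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    if vectors.shape != (len(sidecar["row_index"]), sidecar["dim"]):
        raise ValueError("embedding cache sidecar does not match matrix shape")
    return EmbeddingMatrix(
        vectors=vectors,
        row_index=list(sidecar["row_index"]),
        unit_norm=bool(sidecar["unit_norm"]),
    )
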