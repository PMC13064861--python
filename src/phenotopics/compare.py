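"""Cross-condition comparison of two topic solutions.

Topics from two independently fitted conditions are compared by the cosine
similarity of their *semantic centroids* (mean sentence embedding of each
topic, same embedding model for both conditions).  Pairs above a similarity
threshold tau are matched greedily 1:1 (iteratively take the global maximum,
remove both topics); matched pairs plus condition-specific leftovers form a
merged theme x condition contingency table, tested for independence with a
Pearson chi-squared test.  Prevalence tables normalize per-topic sentence
counts to percentages of each condition's total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

#: similarity threshold for declaring two topics the same experiential theme
DEFAULT_TAU = 0.85


@dataclass
class ThemeMatch:
    topic_a: int
    topic_b: int
    similarity: float
    tau: float


@dataclass
class MergedContingency:
    themes: list[str]
    counts: np.ndarray  # (n_themes, 2) int
    outliers_excluded: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.themes, columns=["A", "B"])


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class PrevalenceTable:
    rows: list[tuple[str, int, float]]  # (topic label, count, percentage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["topic", "sentence_count", "percentage"]
        )


def topic_centroid(topic_embeddings: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the topic's sentence embeddings (not re-normalized;
    downstream cosine handles scale)."""
    X = np.asarray(topic_embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("topic has no embeddings")
    return X.mean(axis=0)


def similarity_matrix(centroids_a: np.ndarray, centroids_b: np.ndarray) -> np.ndarray:
    """K_A x K_B matrix of centroid cosine similarities."""
    A = np.asarray(centroids_a, dtype=float)
    B = np.asarray(centroids_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("centroid dimensionality mismatch")
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm centroid")
    return (A / na) @ (B / nb).T


def greedy_match(sim: np.ndarray, tau: float = DEFAULT_TAU) -> list[ThemeMatch]:
    """1:1 greedy matching: repeatedly take the highest-similarity pair with
    similarity >= tau and remove its row and column.  Ties break on the lowest
    (row, column) index.  Output is sorted by similarity descending."""
    S = np.asarray(sim, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity matrix contains non-finite entries")
    S = S.copy()
    matches: list[ThemeMatch] = []
    alive_rows = set(range(S.shape[0]))
    alive_cols = set(range(S.shape[1]))
    while alive_rows and alive_cols:
        best = None
        for i in sorted(alive_rows):
            for j in sorted(alive_cols):
                if S[i, j] >= tau and (best is None or S[i, j] > S[best[0], best[1]]):
                    best = (i, j)
        if best is None:
            break
        i, j = best
        matches.append(ThemeMatch(topic_a=i, topic_b=j, similarity=float(S[i, j]), tau=tau))
        alive_rows.discard(i)
        alive_cols.discard(j)
    return matches


def merge_themes(
    matches: Sequence[ThemeMatch],
    counts_a: Mapping[int, int],
    counts_b: Mapping[int, int],
    labels_a: Mapping[int, str] | None = None,
    labels_b: Mapping[int, str] | None = None,
    exclude_outliers: bool = True,
) -> MergedContingency:
    """Build the merged theme x condition table.

    Row order: matched pairs (by similarity, as given), then unmatched topics
    of condition A, then of condition B.  Topic id -1 rows (outliers) are
    dropped when ``exclude_outliers``.
    """
    labels_a = labels_a or {}
    labels_b = labels_b or {}
    matched_a = {m.topic_a for m in matches}
    matched_b = {m.topic_b for m in matches}
    for m in matches:
        if m.topic_a not in counts_a or m.topic_b not in counts_b:
            raise KeyError(f"matched topic missing from counts: {m}")
    themes: list[str] = []
    rows: list[tuple[int, int]] = []

    def _name(side: Mapping[int, str], default: str, tid: int) -> str:
        return side.get(tid, f"{default}{tid}")

    for m in matches:
        themes.append(
            f"{_name(labels_a, 'A', m.topic_a)} | {_name(labels_b, 'B', m.topic_b)}"
        )
        rows.append((counts_a[m.topic_a], counts_b[m.topic_b]))
    for tid in sorted(counts_a):
        if tid in matched_a or (exclude_outliers and tid == -1):
            continue
        themes.append(_name(labels_a, "A", tid))
        rows.append((counts_a[tid], 0))
    for tid in sorted(counts_b):
        if tid in matched_b or (exclude_outliers and tid == -1):
            continue
        themes.append(_name(labels_b, "B", tid))
        rows.append((0, counts_b[tid]))
    return MergedContingency(
        themes=themes,
        counts=np.asarray(rows, dtype=np.int64),
        outliers_excluded=exclude_outliers,
    )


def chi_square_independence(table: MergedContingency) -> ChiSquareResult:
    """Pearson chi-squared test of independence on the merged table, without
    continuity correction; df = (rows - 1)(cols - 1)."""
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )


def _round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence(
    counts: Mapping[int, int] | Mapping[str, int], labels: Mapping[int, str] | None = None
) -> PrevalenceTable:
    """Per-topic sentence counts as percentages of the condition total,
    rounded half-up to 2 decimals.  Outliers participate as their own row."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("total sentence count is zero")
    labels = labels or {}
    rows = []
    for tid, count in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0]))):
        name = labels.get(tid, str(tid)) if isinstance(tid, int) else str(tid)
        rows.append((name, int(count), _round_half_up(100.0 * count / total)))
    return PrevalenceTable(rows=rows)


def topic_dendrogram(centroids: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of topic centroids under cosine distance
    (1 - cosine).  Returns the scipy linkage matrix (K-1 merges)."""
    C = np.asarray(centroids, dtype=float)
    if C.shape[0] < 2:
        raise ValueError("need at least 2 centroids for a dendrogram")
    dist = pdist(C, metric="cosine")
    return linkage(dist, method=method)


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str] | None = None) -> str:
    """Render a linkage matrix as a Newick-style nested string with branch
    lengths derived from merge heights."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1
    names = list(leaf_names) if leaf_names else [str(i) for i in range(n)]
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: names[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + Z.shape[0] - 1] + ";"


@dataclass
class ComparisonResult:
    matches: list[ThemeMatch]
    table: MergedContingency
    chi_square: ChiSquareResult
    similarity: np.ndarray = field(default=None)  # type: ignore[assignment]


def compare_conditions(
    centroids_a: np.ndarray,
    centroids_b: np.ndarray,
    counts_a: Mapping[int, int],
    counts_b: Mapping[int, int],
    tau: float = DEFAULT_TAU,
    labels_a: Mapping[int, str] | None = None,
    labels_b: Mapping[int, str] | None = None,
) -> ComparisonResult:
    """similarity -> greedy match -> merged table -> chi-squared, end to end."""
    sim = similarity_matrix(centroids_a, centroids_b)
    matches = greedy_match(sim, tau)
    table = merge_themes(matches, counts_a, counts_b, labels_a, labels_b)
    return ComparisonResult(
        matches=matches,
        table=table,
        chi_square=chi_square_independence(table),
        similarity=sim,
    )


def save_matches(matches: Sequence[ThemeMatch], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "topic_a": m.topic_a,
                    "topic_b": m.topic_b,
                    "similarity": m.similarity,
                    "tau": m.tau,
                }
                for m in matches
            ],
            indent=2,
        ),
        encoding="utf-8",
    )
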