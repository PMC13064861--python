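# Methods

`phenotopics` analyses open-ended experiential (phenomenological) reports —
free text written by participants describing a subjective experience — by
clustering sentence embeddings into *experiential topics* and quantifying the
quality, stability and cross-condition structure of the resulting solution.
This note documents the models and procedures, the defaults and why they were
chosen, and what the synthetic test data do and do not demonstrate.

## Unit of analysis and preprocessing

A report typically touches several experiential facets, so the modelling unit
is the sentence. Preprocessing is:

1. **Normalization** (optional): a pluggable text cleaner, `text -> text`,
   applied report-wise. The default is the identity. A local generative-model
   cleaner can be plugged in; nothing in the package requires one.
2. **Segmentation**: a rule-based punctuation segmenter. Boundaries are runs
   of `.`, `!`, `?` or `…` (optionally followed by closing quotes/brackets)
   before whitespace; a small abbreviation list (`e.g.`, `i.e.`, `Dr.`, ...)
   suppresses false breaks. Text without any boundary is a single sentence.
3. **Filtering**: sentences with fewer than two word tokens are dropped (a
   "word" is a whitespace token containing at least one alphanumeric
   character), and exact duplicates — after casefolding and whitespace
   collapse — are reduced to the first occurrence. Fuzzy deduplication is
   deliberately out of scope. The filter is idempotent.

## Embeddings

Sentences are embedded by a pluggable backend and L2-normalized once at
creation, so cosine similarity is a dot product everywhere downstream.
Whether to normalize before clustering is genuinely open; we normalize by
default and expose the flag.

The production target is a 1024-dimensional sentence transformer (optional
dependency, requires a downloaded model). All testing and simulation uses the
`HashedProjectionBackend`: token counts hashed into 4096 buckets (stable MD5
hashing, not process-salted), projected by a seeded Gaussian matrix and
normalized. It is deterministic, dimension-configurable (default 256 — high
enough that random projections of disjoint vocabularies stay near-orthogonal
for any seed), and
preserves lexical overlap: sentences sharing vocabulary are closer in
expectation than disjoint-vocabulary sentences. It has no contextual
semantics — a deliberate trade: the pipeline's geometry can be tested
end-to-end offline, but nothing about the mock certifies the behaviour of a
particular transformer model on real language.

## Topic model

UMAP (cosine metric, seeded) reduces the embeddings to `n_components`
dimensions; HDBSCAN (Euclidean in the reduced space) clusters them. The
number of topics K is emergent; points in no dense region are labelled `-1`
(outliers). `allow_single_cluster` is enabled so a corpus that is one dense
theme is a valid one-topic solution rather than all-noise.

Outliers can optionally be reassigned: each `-1` point moves to the topic
whose centroid (mean of *original-space* unit embeddings, not reduced-space)
is most cosine-similar, if that similarity reaches a threshold (default 0.0,
i.e. nearest centroid always assigns when the stage is enabled). The stage is
off by default: published applications of this design retain a nontrivial
outlier class, so reassignment is exposed as an explicit choice. Reassignment
never changes existing topic members and never increases the outlier count.

## Keyword representation

Per topic, three keyword views over a lowercased unigram vocabulary with the
scikit-learn English stopword list removed:

- **c-TF-IDF**: `w(t, c) = tf(t, c) * log(1 + A / f_t)` with `tf(t, c)` the
  term count in topic class `c`, `f_t` the term's total count over classes,
  and `A` the average token count per class. Ties break lexicographically.
- **Embedding ranking**: the top-30 c-TF-IDF candidates re-ranked by cosine
  of the bare term's embedding (same backend as sentences) to the topic
  centroid.
- **MMR**: greedy maximal marginal relevance over the same candidates,
  `argmax λ·cos(term, centroid) − (1−λ)·max cos(term, selected)`, λ = 0.5
  by default. λ = 1 reduces exactly to the embedding ranking.

Representative sentences are the topic members most cosine-similar to the
topic centroid (default 3). Candidate-pool size (30), list length (10) and λ
are configuration, not constants.

## Coherence

- **Embedding coherence** `C_embed`: for topic `T_k` with `N_k` members,
  `C_intra(T_k) = (1/C(N_k,2)) Σ_{i<j} cos(e_i, e_j)`, computed exactly (no
  pair sampling — fine at corpus scale n ≈ 10³), and `C_embed` is the
  **unweighted** mean of `C_intra` over the K non-outlier topics. Topics need
  `N_k ≥ 2`; the outlier class never contributes.
- **Word coherence** `C_v`: boolean sliding-window co-occurrence counts over
  the tokenized sentences (window 110, the standard default from the
  coherence literature; documents shorter than the window form one window),
  NPMI between each topic's top 10 words with smoothing ε = 1e−12 guarding
  log(0), perfect co-occurrence defined as NPMI = 1, each word's NPMI context
  vector over the top-word set (diagonal 1), pairwise cosine similarities of
  context vectors averaged within a topic, topics averaged to one score.
  Reference documents are the sentences — the modelling unit — rather than
  reconstituted reports; the choice is flagged because either reading is
  defensible.

## Hyperparameter optimization

Five hyperparameters are searched: `n_components`, `n_neighbors`, `min_dist`
(UMAP) and `min_cluster_size`, `min_samples` (HDBSCAN). Both coherence
metrics are maximized jointly; the exact Pareto front (non-dominated set
under (≥, ≥) with one strict inequality) is extracted and the selected
configuration is the front member with maximal `C_embed` — embedding
coherence judges the semantic geometry directly — with ties broken by higher
`C_v`, then fewer topics, then a config hash for full determinism.

The sampler is a seeded uniform random search (the package's evolutionary-
sampler slot is pluggable; random search is the provided, dependency-free
sampler). Default ranges — `n_components` 2–30, `n_neighbors` 5–50,
`min_dist` 0–0.5, `min_cluster_size` 5–50, `min_samples` 1–`min_cluster_size`
— bracket the configurations such report corpora tend to select while staying
desk-scale. Degenerate trials (no clusters, or a topic with fewer than two
members) are recorded as invalid and excluded from the front rather than
given sentinel scores. Default 100 trials; the tests use 3–8.

## Bootstrap stability

100 iterations (default); each refits the reduce→cluster stack on a random
80% subsample drawn without replacement, with a fresh per-iteration UMAP seed
derived from the master seed. Bootstrap topics are aligned to the reference
solution by **best-match** centroid cosine in original embedding space: for
each reference topic, the maximum similarity over bootstrap centroids.
One-to-many matches are allowed — this measures whether a semantically
equivalent centre re-emerges, not an assignment problem, and deliberately not
sentence-level reassignment stability. Iterations yielding no clusters are
excluded and counted; more than 50% failures raises. Means and SDs are
reported per topic (across iterations) and overall (mean of per-iteration
means).

## Labelling

A deterministic prompt is assembled from the three keyword lists (rank order
preserved — permuting a list changes the prompt hash) and the representative
sentences, and handed to a pluggable generative backend. Backends run locally
by contract: report text never leaves the machine. Multiple attempts per
topic are retained so wording stability can be inspected by a human; the
package does not judge semantic equivalence of label variants automatically.
A backend failure falls back to the topic's top-3 c-TF-IDF keywords joined by
`/`, flagged. Labelling is read-only: assignments, counts and coherence are
bit-identical before and after.

## Cross-condition comparison

Each topic's *semantic centroid* is the arithmetic mean of its sentence
embeddings (original space; not re-normalized — cosine handles scale).
The K_A × K_B centroid cosine matrix is matched greedily 1:1: repeatedly take
the global maximum entry ≥ τ (default τ = 0.85), record the pair, delete its
row and column. Ties break at the lowest (row, column) index for determinism.
Matched pairs plus unmatched condition-specific topics form the merged
theme × condition contingency table; outlier rows are excluded (they are
unassigned sentences, not themes). Independence is tested with the Pearson
chi-squared statistic, no continuity correction, df = (rows − 1)(cols − 1).
Prevalence tables report per-topic counts as percentages of the condition
total, rounded half-up to two decimals (outliers included as their own row);
percentages per condition sum to 100 ± 0.05.

Topic dendrograms use average-linkage agglomerative clustering on cosine
distance (1 − cosine) of topic centroids; centroids in *reduced* space are
the documented default for dendrograms (matching how such figures are
usually drawn), while cross-condition matching uses original-space centroids.
Both are exposed. Label-string matching across conditions is deliberately
unsupported: labels vary with generative-backend wording while centroids do
not.

## Synthetic data

The generator emulates the structure of real report corpora: unequal topic
sizes (default 200/120/90/60/40), ~9% outliers, reports of 1–10 sentences,
6–14 words per sentence (mean report length ≈ 25 words), per-topic disjoint
content vocabularies mixed (85/15) with a shared function-word pool, and
outlier sentences mixing all vocabularies. The embedding generator plants K
Gaussian clusters at orthonormalized random centres on the unit sphere —
Gaussian-on-sphere rather than von Mises–Fisher for simplicity — with the
within-cluster spread scaled so centre separation is `separation` spreads
(default 8, calibrated to be decisively recoverable), plus uniform-sphere
outliers.

What passing on this data shows: the pipeline's stages compose correctly,
planted structure is recovered (ARI ≥ 0.8 end-to-end; ≥ 0.9 on the separated
embedding cloud), stable solutions score ≥ 0.95 bootstrap similarity, and
split halves of one dataset re-match at τ = 0.85. What it does not show:
behaviour on real language — polysemy, context-dependence, topics with
overlapping vocabulary, annotator-relevant nuance — which depends on the
production embedding model.

## Numerical choices and degenerate inputs

- Cosine of a zero vector is an error everywhere (undefined, never silently 0).
- `c_intra` of a singleton topic is an error (undefined binomial
  denominator), surfaced with the topic id; in optimization it marks the
  trial invalid instead.
- Fewer points than `min_cluster_size` yields an all-outlier solution with a
  warning, not an exception.
- NPMI smoothing ε = 1e−12; joint probability 1 is defined as NPMI = 1.
- All stochastic stages (UMAP, sampler, bootstrap, generators) take explicit
  seeds; derived seeds come from a seeded `numpy` generator and stay below
  2³¹.

## Problem sizes used in the shipped checks

The reproducibility script and test suite run at desk scale, chosen as the
smallest sizes at which every property is decisively exercised: the default
synthetic corpus (~560 sentences, 5 topics), a 600-point / 4-cluster cloud
for the 100-iteration bootstrap, 50 random fixtures for the coherence
oracle, and 100 random score sets for the Pareto oracle. The published-count
contingency and prevalence computations use the original study's printed
tables as input, which is exact at any scale.

## Known limitations

- The quality ceiling is the embedding backend; the shipped deterministic
  backend is lexical only.
- Random-search optimization explores less efficiently than an evolutionary
  multi-objective sampler at equal trial counts; the audit trail and Pareto
  logic are sampler-agnostic.
- C_v is sensitive to window size on very short corpora (most sentences are
  shorter than the 110-token window, collapsing it to per-sentence
  co-occurrence — acceptable for sentence-unit corpora, documented here).
- Greedy 1:1 matching is order-dependent by design (it mirrors the published
  procedure); it is not a maximum-weight bipartite assignment.
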