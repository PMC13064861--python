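"""Score a topic solution with both coherence metrics and run a small
multi-objective hyperparameter search with Pareto selection.
"""

import phenotopics as pt
from phenotopics.representation import tokenize

spec = pt.SyntheticSpec(K=3, sizes=(120, 90, 60), outlier_frac=0.0, seed=2)
reports, _ = pt.sample_corpus(spec)
corpus = pt.build_corpus(reports)
backend = pt.hashed_projection_backend(seed=2)
embeddings = pt.embed_corpus(corpus, backend)

# score one fixed configuration
result = pt.evaluate_config(corpus, embeddings, pt.TopicModelConfig(seed=2))
print(
    f"fixed config: K={result.n_topics} "
    f"C_embed={result.scores.c_embed:.3f} C_v={result.scores.c_v:.3f}"
)

# small random search maximizing (C_embed, C_v) jointly
space = pt.SearchSpace(
    n_components=(3, 8), n_neighbors=(10, 25), min_cluster_size=(10, 30),
    n_trials=6, sampler_seed=2,
)
trials, front, best = pt.optimize(corpus, embeddings, space)
print(f"{sum(t.valid for t in trials)}/{len(trials)} valid trials, "
      f"Pareto front size {len(front.trials)}")
print(
    f"selected: K={best.n_topics} C_embed={best.scores.c_embed:.3f} "
    f"C_v={best.scores.c_v:.3f} (highest C_embed on the front)"
)
# C_embed is mean within-topic pairwise embedding cosine (semantic
# compactness); C_v is sliding-window NPMI context-vector coherence of each
# topic's top words (lexical interpretability). Selection prioritizes C_embed.
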