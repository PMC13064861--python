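"""Extract per-topic keywords (c-TF-IDF, embedding-ranked, MMR),
representative sentences, and short labels from the mock backend.
"""

import phenotopics as pt

spec = pt.SyntheticSpec(seed=3)
reports, _ = pt.sample_corpus(spec)
corpus = pt.build_corpus(reports)
backend = pt.hashed_projection_backend(seed=3)
embeddings = pt.embed_corpus(corpus, backend)
assignment = pt.fit_topics(embeddings, pt.TopicModelConfig(seed=3))

reps = pt.represent_topics(corpus, assignment, embeddings, backend)
labels = pt.label_topics(reps, corpus, pt.MockLabelBackend(), n_attempts=2)

for rep, label in zip(reps, labels):
    ctfidf_top = ", ".join(t for t, _ in rep.keywords_ctfidf[:5])
    print(f"topic {rep.topic_id}: label='{label.label}'")
    print(f"  top c-TF-IDF keywords: {ctfidf_top}")
    print(f"  representative: {rep.representative_texts[0][:60]}...")
# Each topic's keywords come from its class-level term statistics; the label
# is the backend's synthesis of the keyword sets + representative sentences
# (here the deterministic mock: top-3 keywords joined by '/').
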