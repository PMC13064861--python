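"""c-TF-IDF keyword weighting, embedding/MMR re-ranking, representatives."""

import math

import numpy as np
import pytest

import phenotopics as pt
from phenotopics.corpus_io import Corpus, SentenceRecord
from phenotopics.representation import (
    ClassTermMatrix,
    build_class_term_matrix,
    ctfidf,
    embed_rank_keywords,
    mmr_select,
    representative_sentences,
    top_keywords,
)


def corpus_from(texts):
    sentences = [
        SentenceRecord(f"s{i}", f"r{i}", 0, t, len(t.split()))
        for i, t in enumerate(texts)
    ]
    return Corpus(condition="HS", sentences=sentences, n_reports=len(texts))


def assignment(labels, K):
    return pt.TopicAssignment(labels=np.asarray(labels), K=K)


class TestClassTermMatrix:
    def test_single_topic_counts(self):
        corpus = corpus_from(["red light", "red shapes"])
        m = build_class_term_matrix(corpus, assignment([0, 0], 1), stopwords=frozenset())
        counts = dict(zip(m.vocabulary, m.counts[0]))
        assert counts == {"red": 2, "light": 1, "shapes": 1}

    def test_stopwords_removed(self):
        corpus = corpus_from(["the red light"])
        m = build_class_term_matrix(corpus, assignment([0], 1), stopwords=frozenset({"the"}))
        assert "the" not in m.vocabulary

    def test_outlier_sentences_excluded(self):
        corpus = corpus_from(["red light", "noise words"])
        m = build_class_term_matrix(corpus, assignment([0, -1], 1), stopwords=frozenset())
        assert "noise" not in m.vocabulary

    def test_two_topic_hand_tally(self):
        corpus = corpus_from(
            ["calm music calm", "music peace", "deep calm",
             "spiral light", "light light spiral", "vivid spiral"]
        )
        m = build_class_term_matrix(
            corpus, assignment([0, 0, 0, 1, 1, 1], 2), stopwords=frozenset()
        )
        tally = {
            (k, m.vocabulary[j]): int(m.counts[k, j])
            for k in range(2)
            for j in range(len(m.vocabulary))
            if m.counts[k, j]
        }
        assert tally == {
            (0, "calm"): 3, (0, "music"): 2, (0, "peace"): 1, (0, "deep"): 1,
            (1, "spiral"): 3, (1, "light"): 3, (1, "vivid"): 1,
        }

    def test_empty_vocabulary_rejected(self):
        corpus = corpus_from(["the and of"])
        with pytest.raises(ValueError):
            build_class_term_matrix(corpus, assignment([0], 1))


class TestCtfidf:
    def test_class_exclusive_term(self):
        m = ClassTermMatrix(
            counts=np.array([[3, 0], [0, 2]]), vocabulary=["only_a", "only_b"],
            topic_ids=[0, 1],
        )
        w = ctfidf(m)
        assert w[0, 0] > 0 and w[1, 0] == 0
        assert w[1, 1] > 0 and w[0, 1] == 0

    def test_hand_evaluated_formula(self):
        # counts [[2,1,0],[0,1,2]]: A = 6/2 = 3; f = (2,2,2)
        m = ClassTermMatrix(
            counts=np.array([[2, 1, 0], [0, 1, 2]]),
            vocabulary=["x", "y", "z"], topic_ids=[0, 1],
        )
        w = ctfidf(m)
        idf = math.log(1 + 3 / 2)
        np.testing.assert_allclose(
            w, np.array([[2, 1, 0], [0, 1, 2]]) * idf, atol=1e-12
        )

    def test_uniform_term_has_equal_weight_everywhere(self):
        m = ClassTermMatrix(
            counts=np.array([[5, 1], [5, 3], [5, 0]]),
            vocabulary=["same", "other"], topic_ids=[0, 1, 2],
        )
        w = ctfidf(m)
        assert w[0, 0] == w[1, 0] == w[2, 0] > 0

    def test_ranking_invariant_to_corpus_duplication(self):
        counts = np.array([[4, 2, 1], [1, 0, 5]])
        m1 = ClassTermMatrix(counts, ["a", "b", "c"], [0, 1])
        m2 = ClassTermMatrix(counts * 2, ["a", "b", "c"], [0, 1])
        for k in range(2):
            r1 = np.argsort(-ctfidf(m1)[k], kind="stable")
            r2 = np.argsort(-ctfidf(m2)[k], kind="stable")
            np.testing.assert_array_equal(r1, r2)


class TestTopKeywords:
    def _matrix(self, counts, vocab):
        return ClassTermMatrix(np.asarray(counts), vocab, list(range(len(counts))))

    def test_exclusive_term_is_top(self):
        m = self._matrix([[5, 1], [0, 4]], ["exclusive", "shared"])
        w = ctfidf(m)
        assert top_keywords(w, m, 0, 1)[0][0] == "exclusive"

    def test_full_ranking_when_n_equals_vocab(self):
        m = self._matrix([[2, 3, 1]], ["a", "b", "c"])
        w = ctfidf(m)
        assert [t for t, _ in top_keywords(w, m, 0, 3)] == ["b", "a", "c"]

    def test_tie_broken_lexicographically(self):
        m = self._matrix([[2, 2]], ["beta", "alpha"])
        w = ctfidf(m)
        assert [t for t, _ in top_keywords(w, m, 0, 2)] == ["alpha", "beta"]

    def test_oversized_n_returns_all_with_warning(self, caplog):
        m = self._matrix([[1, 1]], ["a", "b"])
        with caplog.at_level("WARNING"):
            out = top_keywords(ctfidf(m), m, 0, 10)
        assert len(out) == 2


class TestEmbedRankKeywords:
    def test_centroid_aligned_candidate_first(self, mock_backend):
        candidates = ["calm", "spiral", "music"]
        centroid = mock_backend.embed(["calm"])[0]
        ranked = embed_rank_keywords(candidates, centroid, mock_backend, 3)
        assert ranked[0][0] == "calm"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_single_candidate(self, mock_backend):
        centroid = mock_backend.embed(["anything"])[0]
        assert embed_rank_keywords(["only"], centroid, mock_backend, 1)[0][0] == "only"

    def test_matches_brute_force_order(self, mock_backend):
        candidates = ["calm", "spiral", "music", "light"]
        centroid = mock_backend.embed(["calm music drifting"])[0]
        ranked = [t for t, _ in embed_rank_keywords(candidates, centroid, mock_backend, 4)]
        sims = {
            t: pt.cosine(mock_backend.embed([t])[0], centroid) for t in candidates
        }
        expected = sorted(candidates, key=lambda t: (-sims[t], t))
        assert ranked == expected


class TestMMR:
    def test_lambda_one_reduces_to_relevance_ranking(self, mock_backend):
        candidates = ["calm", "spiral", "music", "light"]
        vecs = np.asarray(mock_backend.embed(candidates))
        query = mock_backend.embed(["calm music"])[0]
        mmr = [t for t, _ in mmr_select(candidates, vecs, query, lam=1.0, n=4)]
        embed = [t for t, _ in embed_rank_keywords(candidates, query, mock_backend, 4)]
        assert mmr == embed

    def test_duplicate_candidate_pushed_back(self):
        # two identical candidates: after picking one, full redundancy (cos=1)
        # forces the second pick to the distinct term
        vecs = np.array([[0.9397, 0.342], [0.9397, 0.342], [0.9, -0.43589]])
        out = mmr_select(["dupA", "dupB", "other"], vecs, np.array([1.0, 0]), lam=0.5, n=2)
        assert [t for t, _ in out] == ["dupA", "other"]

    def test_matches_hand_run_greedy_trace(self):
        # 5 candidates in 2-d; lam=0.6; greedy trace run by hand
        vecs = np.array(
            [[1, 0], [0.95, 0.31225], [0, 1], [0.7071, 0.7071], [-1, 0]], dtype=float
        )
        query = np.array([1.0, 0.0])
        out = mmr_select(["a", "b", "c", "d", "e"], vecs, query, lam=0.6, n=3)
        # relevance: a=1, b=.95, c=0, d=.7071, e=-1 -> first pick a
        # 2nd: b: .6*.95-.4*.95=.57-.38=.19 ; c: 0-.4*0=0 ; d: .6*.7071-.4*.7071=.1414; e: -.6-.4*(-1)=-.2
        #  -> b
        # 3rd: c: -.4*max(0,.31225)=-.1249 ; d: .1414... redundancy d max(cos(d,a)=.7071, cos(d,b)=~.893) -> .6*.7071-.4*.893=.0671
        #  -> d
        assert [t for t, _ in out] == ["a", "b", "d"]

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mmr_select(["a"], np.array([[1.0, 0]]), np.array([1.0, 0]), lam=1.5, n=1)


class TestRepresentativeSentences:
    def _setup(self, mock_backend):
        corpus = corpus_from(["calm music peace", "spiral light vivid", "calm peace quiet"])
        emb = pt.embed_corpus(corpus, mock_backend)
        return corpus, emb

    def test_centroid_sentence_ranks_first(self, mock_backend):
        corpus, emb = self._setup(mock_backend)
        asg = assignment([0, 0, 0], 1)
        ids = representative_sentences(corpus, asg, emb, 0, 1)
        centroid = emb.vectors.mean(axis=0)
        sims = [pt.cosine(v, centroid) for v in emb.vectors]
        assert ids == [f"s{int(np.argmax(sims))}"]

    def test_n_at_least_topic_size_returns_all(self, mock_backend):
        corpus, emb = self._setup(mock_backend)
        asg = assignment([0, 0, 0], 1)
        assert set(representative_sentences(corpus, asg, emb, 0, 10)) == {"s0", "s1", "s2"}

    def test_empty_topic_rejected(self, mock_backend):
        corpus, emb = self._setup(mock_backend)
        asg = assignment([0, 0, 0], 1)
        with pytest.raises(ValueError):
            representative_sentences(corpus, asg, emb, 1, 1)


def test_represent_topics_is_deterministic(synthetic_pipeline):
    p = synthetic_pipeline
    reps1 = pt.represent_topics(p["corpus"], p["assignment"], p["embeddings"], p["backend"])
    reps2 = pt.represent_topics(p["corpus"], p["assignment"], p["embeddings"], p["backend"])
    assert [r.keywords_ctfidf for r in reps1] == [r.keywords_ctfidf for r in reps2]
    assert [r.keywords_mmr for r in reps1] == [r.keywords_mmr for r in reps2]
    assert [r.representatives for r in reps1] == [r.representatives for r in reps2]
    for r in reps1:
        scores = [s for _, s in r.keywords_ctfidf]
        assert scores == sorted(scores, reverse=True)
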