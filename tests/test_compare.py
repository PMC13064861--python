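"""Cross-condition matching, merged contingency inference, prevalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

import phenotopics as pt
from phenotopics.compare import (
    MergedContingency,
    linkage_to_newick,
    prevalence,
    topic_centroid,
)


class TestTopicCentroid:
    def test_identical_rows(self):
        np.testing.assert_allclose(
            topic_centroid(np.array([[1.0, 2], [1, 2]])), [1, 2]
        )

    def test_two_unit_vectors(self):
        np.testing.assert_allclose(
            topic_centroid(np.array([[1.0, 0], [0, 1.0]])), [0.5, 0.5]
        )

    def test_hand_mean_of_three(self):
        X = np.array([[1.0, 2, 3], [4, 5, 6], [1, 1, 0]])
        np.testing.assert_allclose(topic_centroid(X), [2, 8 / 3, 3])

    def test_empty_topic_rejected(self):
        with pytest.raises(ValueError):
            topic_centroid(np.empty((0, 3)))


class TestSimilarityMatrix:
    def test_identical_lists_have_unit_diagonal(self):
        C = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        np.testing.assert_allclose(np.diag(pt.similarity_matrix(C, C)), 1.0)

    def test_orthogonal_sets_zero_matrix(self):
        A = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        B = np.array([[0, 0, 1.0, 0], [0, 0, 0, 1.0]])
        np.testing.assert_allclose(pt.similarity_matrix(A, B), 0.0, atol=1e-12)

    def test_2x3_matches_entrywise_cosine(self):
        rng = np.random.default_rng(0)
        A, B = rng.standard_normal((2, 5)), rng.standard_normal((3, 5))
        S = pt.similarity_matrix(A, B)
        for i in range(2):
            for j in range(3):
                assert S[i, j] == pytest.approx(pt.cosine(A[i], B[j]), abs=1e-12)

    def test_zero_centroid_rejected(self):
        with pytest.raises(ValueError):
            pt.similarity_matrix(np.zeros((1, 3)), np.ones((1, 3)))


def brute_greedy(S, tau):
    """Direct transcription of the iterate-max rule."""
    S = S.copy().astype(float)
    out = []
    rows, cols = set(range(S.shape[0])), set(range(S.shape[1]))
    while True:
        cand = [
            (S[i, j], i, j) for i in rows for j in cols if S[i, j] >= tau
        ]
        if not cand:
            return out
        _, i, j = max(cand, key=lambda t: (t[0], -t[1], -t[2]))
        out.append((i, j, S[i, j]))
        rows.remove(i)
        cols.remove(j)


class TestGreedyMatch:
    def test_hand_run_two_pair_case(self):
        S = np.array([[0.9, 0.3], [0.4, 0.88]])
        matches = pt.greedy_match(S, tau=0.85)
        assert [(m.topic_a, m.topic_b, m.similarity) for m in matches] == [
            (0, 0, 0.9),
            (1, 1, 0.88),
        ]

    def test_unreachable_tau_gives_no_matches(self):
        assert pt.greedy_match(np.ones((3, 3)), tau=1.01) == []

    def test_greedy_removal_can_block_second_best(self):
        # row 0 takes column 0 (0.95); row 1's only entry above tau is also
        # column 0 -> no second match
        S = np.array([[0.95, 0.2], [0.90, 0.3]])
        matches = pt.greedy_match(S, tau=0.85)
        assert len(matches) == 1 and matches[0].topic_a == 0

    def test_output_sorted_descending_and_one_to_one(self):
        rng = np.random.default_rng(2)
        S = rng.random((6, 6))
        matches = pt.greedy_match(S, tau=0.3)
        sims = [m.similarity for m in matches]
        assert sims == sorted(sims, reverse=True)
        assert len({m.topic_a for m in matches}) == len(matches)
        assert len({m.topic_b for m in matches}) == len(matches)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_equals_brute_force_on_random_matrices(self, seed, tau):
        S = np.random.default_rng(seed).random((6, 6))
        ours = [(m.topic_a, m.topic_b) for m in pt.greedy_match(S, tau)]
        assert ours == [(i, j) for i, j, _ in brute_greedy(S, tau)]


class TestMergeThemes:
    def test_no_matches_is_block_diagonal(self):
        table = pt.merge_themes([], {0: 5, 1: 7}, {0: 3})
        np.testing.assert_array_equal(table.counts, [[5, 0], [7, 0], [0, 3]])

    def test_all_topics_matched(self):
        matches = [
            pt.ThemeMatch(0, 1, 0.9, 0.85),
            pt.ThemeMatch(1, 0, 0.88, 0.85),
        ]
        table = pt.merge_themes(matches, {0: 5, 1: 7}, {0: 3, 1: 4})
        np.testing.assert_array_equal(table.counts, [[5, 4], [7, 3]])

    def test_outlier_rows_dropped_and_sentences_conserved(self):
        matches = [pt.ThemeMatch(0, 0, 0.9, 0.85)]
        counts_a = {-1: 10, 0: 20, 1: 5}
        counts_b = {-1: 2, 0: 8}
        table = pt.merge_themes(matches, counts_a, counts_b)
        assert table.counts.sum() == (20 + 5) + 8
        assert table.counts[:, 0].sum() == 25 and table.counts[:, 1].sum() == 8

    def test_missing_matched_topic_rejected(self):
        with pytest.raises(KeyError):
            pt.merge_themes([pt.ThemeMatch(3, 0, 0.9, 0.85)], {0: 1}, {0: 1})


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        table = MergedContingency(["a", "b"], np.array([[10, 20], [5, 10]]))
        result = pt.chi_square_independence(table)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_2x2(self):
        # [[10,0],[0,10]]: all expected counts 5 -> sum (O-E)^2/E = 4*25/5 = 20
        table = MergedContingency(["a", "b"], np.array([[10, 0], [0, 10]]))
        result = pt.chi_square_independence(table)
        assert result.statistic == pytest.approx(20.0)
        assert result.df == 1

    def test_matches_textbook_formula_on_small_tables(self):
        # exhaustive small-case oracle over 2x2 integer tables, margins <= 20
        for a in range(1, 6):
            for b in range(1, 6):
                for c in range(1, 6):
                    for d in range(1, 6):
                        O = np.array([[a, b], [c, d]], dtype=float)
                        n = O.sum()
                        E = np.outer(O.sum(1), O.sum(0)) / n
                        expected = ((O - E) ** 2 / E).sum()
                        table = MergedContingency(["x", "y"], O.astype(int))
                        result = pt.chi_square_independence(table)
                        assert result.statistic == pytest.approx(expected, abs=1e-9)
                        assert result.p_value == pytest.approx(
                            chi2_dist.sf(expected, 1), abs=1e-12
                        )

    def test_zero_margin_rejected(self):
        table = MergedContingency(["a", "b"], np.array([[5, 0], [7, 0]]))
        with pytest.raises(ValueError):
            pt.chi_square_independence(table)


class TestPrevalence:
    def test_two_decimal_half_up_rounding(self):
        table = prevalence({0: 1, 1: 2})  # 33.333 -> 33.33, 66.667 -> 66.67
        percentages = {name: p for name, _, p in table.rows}
        assert percentages == {"1": 66.67, "0": 33.33}

    def test_published_style_fraction(self):
        table = prevalence({0: 191, 1: 509})
        by_name = {name: p for name, _, p in table.rows}
        assert by_name["0"] == pytest.approx(27.29)

    def test_zero_count_topic(self):
        table = prevalence({0: 0, 1: 10})
        assert dict((n, p) for n, _, p in table.rows)["0"] == 0.0

    def test_percentages_sum_to_about_100(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            counts = {i: int(c) for i, c in enumerate(rng.integers(1, 500, size=12))}
            total = sum(p for _, _, p in prevalence(counts).rows)
            assert total == pytest.approx(100.0, abs=0.05)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            prevalence({0: 0})


class TestDendrogram:
    def test_identical_centroids_merge_at_zero(self):
        C = np.array([[1.0, 0], [1.0, 0], [0, 1.0]])
        Z = pt.topic_dendrogram(C)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_near_duplicates_merge_first(self):
        C = np.array([[1.0, 0, 0], [0.999, 0.01, 0], [0, 0, 1.0]])
        Z = pt.topic_dendrogram(C)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_k_topics_give_k_minus_1_monotone_merges(self):
        rng = np.random.default_rng(3)
        C = rng.standard_normal((7, 5))
        Z = pt.topic_dendrogram(C)
        assert Z.shape[0] == 6
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_single_centroid_rejected(self):
        with pytest.raises(ValueError):
            pt.topic_dendrogram(np.array([[1.0, 0]]))

    def test_newick_export_names_all_leaves(self):
        C = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        newick = linkage_to_newick(pt.topic_dendrogram(C), ["t0", "t1", "t2"])
        assert newick.endswith(";")
        for leaf in ("t0", "t1", "t2"):
            assert leaf in newick
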