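import numpy as np
import pytest

import adrscore as a
from conftest import naive_scores, random_instance


class TestSimilarityFactors:
    def test_sim_x_takes_max_over_related_drugs(self, toy):
        adj, drug_sim, _ = toy
        val, empty = a.sim_x(adj, drug_sim, alpha=0, beta=1)
        assert val == pytest.approx(0.8) and not empty

    def test_sim_x_leave_one_out_empties_singleton_set(self, toy):
        adj, drug_sim, _ = toy
        val, empty = a.sim_x(adj, drug_sim, alpha=0, beta=0)
        assert val == 0.0 and empty

    def test_sim_y_mirror(self, toy):
        adj, _, se_sim = toy
        assert a.sim_y(adj, se_sim, alpha=0, beta=1) == (pytest.approx(0.5), False)
        assert a.sim_y(adj, se_sim, alpha=0, beta=0) == (0.0, True)

    def test_max_of_several_related(self):
        rel = a.RelationTable(frozenset({("a", "x"), ("b", "x"), ("c", "x"),
                                         ("d", "x"), ("d", "y")}))
        adj = a.build_adjacency(rel)
        S = np.eye(4)
        # similarities of d (index 3) to a, b, c
        S[3, :3] = S[:3, 3] = [0.2, 0.9, 0.4]
        drug_sim = a.SimilarityMatrix(axis=a.Axis.DRUG, metric="cosine", S=S,
                                      vocab=adj.drug_vocab)
        val, _ = a.sim_x(adj, drug_sim, alpha=3, beta=adj.se_vocab.index["x"])
        assert val == pytest.approx(0.9)

    def test_axis_mismatch_is_an_error(self, toy):
        adj, drug_sim, se_sim = toy
        with pytest.raises(ValueError, match="axis"):
            a.sim_x(adj, se_sim, 0, 0)
        with pytest.raises(ValueError, match="axis"):
            a.score_all_pairs(adj, se_sim, drug_sim)


def test_relation_score_is_the_product():
    assert a.relation_score(0.861, 0.857) == pytest.approx(0.738, abs=5e-4)
    assert a.relation_score(0.0, 0.9) == 0.0
    assert a.relation_score(-0.5, -0.4) == pytest.approx(0.2)


class TestScoreAllPairs:
    def test_toy_scores(self, toy):
        adj, drug_sim, se_sim = toy
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        assert sm.score[0, 1] == pytest.approx(0.8 * 0.5)
        assert sm.score[1, 0] == pytest.approx(0.8 * 0.5)
        # known pairs: both related sets empty after exclusion
        assert sm.score[0, 0] == 0.0 and sm.masked[0, 0]

    def test_all_ones_adjacency_has_no_masked_cells(self):
        rel = a.RelationTable(frozenset(
            (d, s) for d in "abc" for s in "xy"))
        adj = a.build_adjacency(rel)
        rng = np.random.default_rng(1)
        SD, SE = rng.normal(size=(3, 3)), rng.normal(size=(2, 2))
        sm = a.score_all_pairs(
            adj,
            a.SimilarityMatrix(axis=a.Axis.DRUG, metric="dot", S=(SD + SD.T) / 2,
                               vocab=adj.drug_vocab),
            a.SimilarityMatrix(axis=a.Axis.SIDE_EFFECT, metric="dot", S=(SE + SE.T) / 2,
                               vocab=adj.se_vocab))
        assert not sm.masked.any()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            adj, drug_sim, se_sim = random_instance(rng, max_drugs=15, max_ses=20)
            sm = a.score_all_pairs(adj, drug_sim, se_sim)
            assert np.allclose(sm.score, naive_scores(adj, drug_sim, se_sim), atol=1e-12)

    def test_known_pair_scores_unchanged_when_its_own_cell_is_dropped(self):
        """Leave-one-out already removed self-evidence: zeroing R[a, b] changes nothing at (a, b)."""
        rng = np.random.default_rng(9)
        adj, drug_sim, se_sim = random_instance(rng, max_drugs=12, max_ses=15)
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        for alpha, beta in zip(*np.nonzero(adj.R)):
            R2 = adj.R.copy()
            R2[alpha, beta] = 0
            if not (R2.any(axis=1).all() and R2.any(axis=0).all()):
                continue
            adj2 = a.AdjacencyMatrix(R=R2, drug_vocab=adj.drug_vocab,
                                     se_vocab=adj.se_vocab)
            sm2 = a.score_all_pairs(adj2, drug_sim, se_sim)
            assert sm2.score[alpha, beta] == sm.score[alpha, beta]

    def test_increasing_a_used_similarity_cannot_decrease_scores(self, toy):
        adj, drug_sim, se_sim = toy
        before = a.score_all_pairs(adj, drug_sim, se_sim).score
        S2 = drug_sim.S.copy()
        S2[0, 1] = S2[1, 0] = 0.95
        after = a.score_all_pairs(
            adj, a.SimilarityMatrix(axis=a.Axis.DRUG, metric="cosine", S=S2,
                                    vocab=adj.drug_vocab), se_sim).score
        assert np.all(after >= before - 1e-15)

    def test_cosine_scores_are_bounded(self, default_run):
        _, model = default_run
        sm = model.score_matrix_
        assert np.all(np.abs(sm.sim_x) <= 1.0) and np.all(np.abs(sm.sim_y) <= 1.0)
        assert np.all(np.abs(sm.score) <= 1.0)
        assert np.all(sm.score[sm.masked] == 0.0)


class TestTopNovelPairs:
    def test_only_unknown_pairs_are_ranked(self, toy):
        adj, drug_sim, se_sim = toy
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        top = a.top_novel_pairs(sm, k=10)  # k beyond the 2 unknown cells: clamp
        assert len(top) == 2
        assert set(zip(top["drug"], top["side_effect"])) == {("a", "y"), ("b", "x")}

    def test_ordering_matches_enumeration(self):
        rng = np.random.default_rng(77)
        adj, drug_sim, se_sim = random_instance(rng, max_drugs=8, max_ses=8)
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        top = a.top_novel_pairs(sm, k=5)
        # brute-force ranking with the same lexicographic tie-break
        cells = [(sm.score[i, j], adj.drug_vocab.terms[i], adj.se_vocab.terms[j])
                 for i in range(adj.shape[0]) for j in range(adj.shape[1])
                 if adj.R[i, j] == 0]
        cells.sort(key=lambda t: (-t[0], t[1], t[2]))
        expect = [(d, s) for _, d, s in cells[:5]]
        assert list(zip(top["drug"], top["side_effect"])) == expect

    def test_k_must_be_positive(self, toy):
        adj, drug_sim, se_sim = toy
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        with pytest.raises(ValueError):
            a.top_novel_pairs(sm, k=0)


def test_pair_counts_are_products():
    counts = a.pair_counts(3, 5)
    assert counts == {"drug_similarity_cells": 9, "se_similarity_cells": 25,
                      "scored_pairs": 15}
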