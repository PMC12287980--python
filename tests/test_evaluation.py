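import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import adrscore as a
from conftest import random_instance


class TestRocAuc:
    def test_perfect_separation(self):
        roc = a.roc_auc([0.9, 0.1], [1, 0])
        assert roc.auc == 1.0
        assert roc.n_pos == 1 and roc.n_neg == 1

    def test_all_tied_scores_give_half(self):
        assert a.roc_auc([0.3] * 6, [1, 0, 1, 0, 0, 1]).auc == pytest.approx(0.5)

    def test_hand_enumerated_concordance(self):
        # of the 4 pos-neg pairs, 3 are concordant
        assert a.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]).auc == pytest.approx(0.75)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            a.roc_auc([0.1, 0.2], [1, 1])

    def test_youden_point_with_tie_takes_smallest_threshold(self):
        # J = 0.5 at thresholds 0.8 and 0.6; the smaller one is reported
        roc = a.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert roc.optimal_threshold == pytest.approx(0.6)
        assert roc.sensitivity_at_opt == pytest.approx(1.0)
        assert roc.specificity_at_opt == pytest.approx(0.5)

    def test_curve_runs_from_origin_to_one_one(self):
        roc = a.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)
        assert roc.thresholds[-1] == -np.inf

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=40), 1)  # heavy ties
            assert a.roc_auc(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-10)


@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_invariant_under_increasing_transform_and_flips_with_labels(seed):
    rng = np.random.default_rng(seed)
    s = np.round(rng.normal(size=30), 1)
    y = rng.integers(0, 2, 30)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    base = a.roc_auc(s, y).auc
    assert a.roc_auc(3.0 * s + 2.0, y).auc == pytest.approx(base, abs=1e-12)
    assert a.roc_auc(np.exp(s), y).auc == pytest.approx(base, abs=1e-12)
    assert a.roc_auc(s, 1 - y).auc == pytest.approx(1.0 - base, abs=1e-12)


def test_trapezoid_and_rank_forms_agree_under_ties():
    rng = np.random.default_rng(8)
    for _ in range(30):
        s = np.round(rng.normal(size=50), 1)
        y = rng.integers(0, 2, 50)
        if y.min() == y.max():
            continue
        assert a.roc_auc(s, y).auc == pytest.approx(a.rank_auc(s, y), abs=1e-10)


class TestLabelPairs:
    def test_counts_match_adjacency(self, toy):
        adj, drug_sim, se_sim = toy
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        s, y = a.label_pairs(sm)
        assert s.size == 4 and y.sum() == 2

    def test_drop_masked_removes_cells(self, toy):
        adj, drug_sim, se_sim = toy
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        s, y = a.label_pairs(sm, drop_masked=True)
        assert s.size == 4 - int(sm.masked.sum())

    def test_shape_mismatch_is_an_error(self, toy):
        adj, drug_sim, se_sim = toy
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        other = a.build_adjacency(a.RelationTable(frozenset({("a", "x")})))
        with pytest.raises(ValueError, match="shape"):
            a.label_pairs(sm, other)


class TestAblation:
    def test_product_mode_reproduces_main_pipeline(self):
        rng = np.random.default_rng(21)
        adj, drug_sim, se_sim = random_instance(rng, max_drugs=12, max_ses=15)
        sm = a.score_all_pairs(adj, drug_sim, se_sim)
        direct = a.roc_auc(*a.label_pairs(sm))
        via_ablation = a.ablation_single_similarity(adj, drug_sim, se_sim, "product")
        assert via_ablation.auc == direct.auc
        assert via_ablation.optimal_threshold == direct.optimal_threshold

    def test_drug_only_signal_favors_sim_x(self):
        """When only drug factors carry signal, ranking by sim_x beats sim_y."""
        cfg = a.SyntheticConfig(n_drugs=40, n_ses=80, n_factors=4, dim=16,
                                noise_sd=0.2, seed=13)
        data = a.generate(cfg)
        drug_sim = a.pairwise_similarity(data.drug_embeddings, "cosine")
        # destroy the side-effect embedding signal entirely
        rng = np.random.default_rng(99)
        shuffled = a.EmbeddingSet(
            axis=a.Axis.SIDE_EFFECT, dim=cfg.dim,
            vectors={t: rng.normal(size=cfg.dim)
                     for t in data.se_embeddings.vectors})
        se_sim = a.pairwise_similarity(shuffled, "cosine")
        adj = a.build_adjacency(data.relations)
        auc_x = a.ablation_single_similarity(adj, drug_sim, se_sim, "sim_x_only").auc
        auc_y = a.ablation_single_similarity(adj, drug_sim, se_sim, "sim_y_only").auc
        assert auc_x > auc_y

    def test_unknown_mode_rejected(self, toy):
        adj, drug_sim, se_sim = toy
        with pytest.raises(ValueError, match="mode"):
            a.ablation_single_similarity(adj, drug_sim, se_sim, "both_only")


def test_held_out_evaluation_recovers_signal(default_run):
    data, model = default_run
    roc = a.held_out_evaluation(model.adjacency_, model.drug_sim_, model.se_sim_,
                                holdout_fraction=0.2, seed=4)
    assert roc.auc > 0.7
    assert roc.n_pos == round(0.2 * model.adjacency_.n_known())
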