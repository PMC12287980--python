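"""scikit-learn-style estimator wrapping the relation-scoring pipeline.

``RelationScorer`` is fit on a known relation table plus per-axis term
embeddings; fitting builds the adjacency, the two within-axis similarity
matrices and the full score matrix. ``decision_function`` exposes relation
scores, ``predict`` thresholds them (strictly), and ``evaluate`` runs the
in-sample ROC and stores the Youden-optimal threshold for later prediction.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .relations import AdjacencyMatrix, RelationTable, build_adjacency
from .embeddings import EmbeddingSet
from .metrics import pairwise_similarity
from .scoring import score_all_pairs, top_novel_pairs
from .evaluate import ROCResult, ablation_single_similarity, label_pairs, roc_auc
from .validate import predict_labels

__all__ = ["RelationScorer"]


class RelationScorer(BaseEstimator):
    """Leave-one-out max-similarity scorer for drug x side-effect pairs.

    Parameters
    ----------
    metric : str, default "cosine"
        Within-axis similarity metric: cosine, euclidean, manhattan, jaccard
        (generalized/Ruzicka) or dot.
    threshold : float or None, default None
        Fixed decision threshold for :meth:`predict`. When None, the
        Youden-optimal threshold from :meth:`evaluate` is used (and must have
        been computed first).
    drop_masked : bool, default False
        Exclude cells whose related set was emptied by leave-one-out exclusion
        from ROC evaluation instead of treating them as score-0 negatives.

    Attributes
    ----------
    adjacency_ : AdjacencyMatrix
        Binary known-relation matrix with induced, sorted vocabularies.
    drug_sim_, se_sim_ : SimilarityMatrix
        Full square within-axis similarity matrices (self-pairs included).
    score_matrix_ : ScoreMatrix
        Relation scores with sim_x/sim_y factors and empty-set masks.
    roc_ : ROCResult
        Set by :meth:`evaluate`.
    optimal_threshold_ : float
        Youden-optimal threshold, set by :meth:`evaluate`.
    """

    def __init__(self, metric: str = "cosine", threshold: float | None = None,
                 drop_masked: bool = False):
        self.metric = metric
        self.threshold = threshold
        self.drop_masked = drop_masked

    def fit(self, relations: RelationTable, drug_embeddings: EmbeddingSet,
            se_embeddings: EmbeddingSet) -> "RelationScorer":
        """Build adjacency, similarity matrices and all-pairs relation scores."""
        adj = build_adjacency(relations)
        self.adjacency_ = adj
        self.drug_sim_ = pairwise_similarity(drug_embeddings, self.metric, adj.drug_vocab)
        self.se_sim_ = pairwise_similarity(se_embeddings, self.metric, adj.se_vocab)
        self.score_matrix_ = score_all_pairs(adj, self.drug_sim_, self.se_sim_)
        self.n_drugs_ = adj.shape[0]
        self.n_ses_ = adj.shape[1]
        return self

    def decision_function(self, pairs: list[tuple[str, str]] | None = None) -> np.ndarray:
        """Relation scores: the full matrix, or a vector for specific term pairs."""
        check_is_fitted(self, "score_matrix_")
        if pairs is None:
            return self.score_matrix_.score
        dv = self.adjacency_.drug_vocab.index
        sv = self.adjacency_.se_vocab.index
        return np.array([self.score_matrix_.score[dv[d], sv[s]] for d, s in pairs])

    def predict(self, pairs: list[tuple[str, str]] | None = None) -> np.ndarray:
        """Binary related/unrelated predictions at the active threshold (strict >)."""
        check_is_fitted(self, "score_matrix_")
        if self.threshold is not None:
            thr = self.threshold
        else:
            check_is_fitted(self, "optimal_threshold_")
            thr = self.optimal_threshold_
        return predict_labels(self.decision_function(pairs), thr)

    def evaluate(self, mode: str = "product") -> ROCResult:
        """In-sample ROC against the fitted adjacency; stores the Youden threshold.

        ``mode`` selects the ranked quantity: "product" (the relation score) or
        the single-factor ablations "sim_x_only" / "sim_y_only".
        """
        check_is_fitted(self, "score_matrix_")
        if mode == "product":
            s, y = label_pairs(self.score_matrix_, drop_masked=self.drop_masked)
            roc = roc_auc(s, y)
        else:
            roc = ablation_single_similarity(
                self.adjacency_, self.drug_sim_, self.se_sim_, mode,
                drop_masked=self.drop_masked)
        if mode == "product":
            self.roc_ = roc
            self.optimal_threshold_ = roc.optimal_threshold
        return roc

    def top_novel(self, k: int = 10):
        """Highest-scoring pairs not present in the fitted relation table."""
        check_is_fitted(self, "score_matrix_")
        return top_novel_pairs(self.score_matrix_, k)
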