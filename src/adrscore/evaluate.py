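"""ROC evaluation of relation scores against the known adjacency.

Every scored cell is labelled positive iff the pair is in the known relation
table, all cells are pooled into one score vector, and a single ROC curve is
computed over the unique score values with the strict "score > threshold"
prediction convention. The operating threshold is Youden-optimal: it maximizes
sensitivity + specificity, i.e. TPR - FPR.

This is deliberately an in-sample evaluation — the same adjacency builds the
related sets and supplies the labels — relying on leave-one-out exclusion to
remove self-evidence. A held-out mode (mask a random fraction of known pairs,
score with the rest, evaluate only on masked-vs-unknown cells) is offered as
the methodologically stricter alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import rankdata

from .relations import AdjacencyMatrix
from .metrics import SimilarityMatrix
from .scoring import ScoreMatrix, score_all_pairs

__all__ = ["ROCResult", "label_pairs", "roc_auc", "rank_auc",
           "ablation_single_similarity", "held_out_evaluation"]


@dataclass(frozen=True)
class ROCResult:
    """A ROC curve with its AUC and the Youden-optimal operating point.

    ``thresholds`` lists the unique score values in descending order followed
    by ``-inf`` (predict everything); ``tpr``/``fpr`` are aligned to it, so the
    curve runs from (0, 0) to (1, 1) under the strict ``score > t`` rule.
    """

    auc: float
    thresholds: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)
    optimal_threshold: float
    sensitivity_at_opt: float
    specificity_at_opt: float
    n_pos: int
    n_neg: int

    def to_report(self) -> dict:
        return {
            "auc": self.auc,
            "optimal_threshold": self.optimal_threshold,
            "sensitivity": self.sensitivity_at_opt,
            "specificity": self.specificity_at_opt,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def label_pairs(scores: ScoreMatrix, adj: AdjacencyMatrix | None = None,
                drop_masked: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Flatten scores and known/unknown labels into aligned vectors.

    Masked cells (empty related set after exclusion) are included as score-0
    cells by default, matching a full all-pairs evaluation; ``drop_masked``
    removes them from both vectors.
    """
    adj = adj if adj is not None else scores.adjacency
    if adj.shape != scores.shape:
        raise ValueError(f"adjacency shape {adj.shape} != score shape {scores.shape}")
    s = scores.score.ravel()
    y = adj.R.ravel().astype(np.int8)
    if drop_masked:
        keep = ~scores.masked.ravel()
        s, y = s[keep], y[keep]
    return s, y


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Build the single ROC curve over unique score values and pick the Youden point.

    The trapezoidal area over the tie-grouped curve is mathematically identical
    to the tie-corrected rank AUC; both are computed and cross-checked. On
    Youden ties the smallest qualifying threshold is reported.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")

    uniq, inv = np.unique(scores, return_inverse=True)
    pos_at = np.bincount(inv, weights=labels, minlength=uniq.size)
    tot_at = np.bincount(inv, minlength=uniq.size)
    neg_at = tot_at - pos_at
    # descending thresholds; at t = uniq_desc[k], positives predicted are those
    # strictly above t, i.e. the cumulative counts of the k values above it
    pos_desc = pos_at[::-1]
    neg_desc = neg_at[::-1]
    tp = np.concatenate(([0.0], np.cumsum(pos_desc)))
    fp = np.concatenate(([0.0], np.cumsum(neg_desc)))
    thresholds = np.concatenate((uniq[::-1], [-np.inf]))
    tpr = tp / n_pos
    fpr = fp / n_neg

    auc_trap = float(np.trapezoid(tpr, fpr))
    auc_rank = rank_auc(scores, labels)
    if abs(auc_trap - auc_rank) > 1e-9:  # the two forms are equal in exact arithmetic
        raise AssertionError(
            f"trapezoidal AUC {auc_trap} and rank AUC {auc_rank} disagree")

    youden = tpr - fpr
    best = int(np.flatnonzero(youden == youden.max())[-1])  # smallest threshold on ties
    return ROCResult(
        auc=auc_trap,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        optimal_threshold=float(thresholds[best]),
        sensitivity_at_opt=float(tpr[best]),
        specificity_at_opt=float(1.0 - fpr[best]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def ablation_single_similarity(
    adj: AdjacencyMatrix,
    drug_sim: SimilarityMatrix,
    se_sim: SimilarityMatrix,
    mode: Literal["sim_x_only", "sim_y_only", "product"] = "product",
    drop_masked: bool = False,
) -> ROCResult:
    """Evaluate ranking by one similarity factor alone, or by their product."""
    sm = score_all_pairs(adj, drug_sim, se_sim)
    if mode == "product":
        ranked = sm.score
    elif mode == "sim_x_only":
        ranked = np.where(sm.empty_x_mask, 0.0, sm.sim_x)
    elif mode == "sim_y_only":
        ranked = np.where(sm.empty_y_mask, 0.0, sm.sim_y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    y = adj.R.ravel().astype(np.int8)
    s = ranked.ravel()
    if drop_masked:
        keep = ~sm.masked.ravel()
        s, y = s[keep], y[keep]
    return roc_auc(s, y)


def held_out_evaluation(
    adj: AdjacencyMatrix,
    drug_sim: SimilarityMatrix,
    se_sim: SimilarityMatrix,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> ROCResult:
    """Mask a random fraction of known pairs, score with the rest, evaluate on them.

    Positives are the held-out known pairs; negatives are the never-known cells.
    The retained known pairs are excluded from evaluation (they were evidence).
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    known = np.flatnonzero(adj.R.ravel())
    n_hold = max(1, int(round(holdout_fraction * known.size)))
    held = rng.choice(known, size=n_hold, replace=False)
    R_train = adj.R.copy().ravel()
    R_train[held] = 0
    R_train = R_train.reshape(adj.shape)
    # vocabularies stay intact: a row/column emptied by masking just yields
    # empty related sets (score 0) rather than shrinking the matrix
    train_adj = AdjacencyMatrix(R=R_train, drug_vocab=adj.drug_vocab, se_vocab=adj.se_vocab)
    sm = score_all_pairs(train_adj, drug_sim, se_sim)
    s = sm.score.ravel()
    y = np.zeros(s.size, dtype=np.int8)
    y[held] = 1
    keep = np.ones(s.size, dtype=bool)
    keep[np.flatnonzero(R_train.ravel())] = False
    return roc_auc(s[keep], y[keep])
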