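"""Leave-one-out max-similarity relation scores for every drug x side-effect pair.

For a query pair (drug alpha, side effect beta):

    sim_x = max over drugs known for beta, excluding alpha, of drug-similarity(alpha, .)
    sim_y = max over side effects known for alpha, excluding beta, of SE-similarity(beta, .)
    relation score = sim_x * sim_y

The exclusion removes the queried entity from its own evidence set, so a known
pair cannot trivially vouch for itself through the self-similarity of 1. When
exclusion empties a related set (a side effect known for exactly one drug,
scored against that drug, or the symmetric case) the factor is 0 and the cell
is flagged in an explicit mask: 0 encodes "no evidence" without inventing a
prior, and the mask keeps such cells auditable downstream.

Negative cosine values are deliberately not clamped; the product of two
negative factors can be positive. With real biomedical term vectors this is
rare, and clamping would silently change metric comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .relations import AdjacencyMatrix, Axis, related_drugs, related_side_effects
from .metrics import SimilarityMatrix

__all__ = [
    "ScoreMatrix",
    "sim_x",
    "sim_y",
    "relation_score",
    "score_all_pairs",
    "top_novel_pairs",
    "pair_counts",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Relation scores plus the two similarity factors and empty-set masks."""

    score: np.ndarray
    sim_x: np.ndarray
    sim_y: np.ndarray
    empty_x_mask: np.ndarray
    empty_y_mask: np.ndarray
    adjacency: AdjacencyMatrix

    def __post_init__(self) -> None:
        shape = self.adjacency.shape
        for name in ("score", "sim_x", "sim_y", "empty_x_mask", "empty_y_mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != adjacency shape {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.score.shape

    @property
    def masked(self) -> np.ndarray:
        """Cells whose score is 0 by convention (empty related set after exclusion)."""
        return self.empty_x_mask | self.empty_y_mask

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: drug, side_effect, sim_x, sim_y, score, known."""
        nd, ns = self.shape
        ii, jj = np.meshgrid(np.arange(nd), np.arange(ns), indexing="ij")
        return pd.DataFrame({
            "drug": np.asarray(self.adjacency.drug_vocab.terms)[ii.ravel()],
            "side_effect": np.asarray(self.adjacency.se_vocab.terms)[jj.ravel()],
            "sim_x": self.sim_x.ravel(),
            "sim_y": self.sim_y.ravel(),
            "score": self.score.ravel(),
            "known": self.adjacency.R.ravel().astype(bool),
        })

    def to_tsv(self, path: str | Path) -> None:
        # %.17g round-trips doubles exactly, so file-based and in-memory
        # downstream stages agree bit-for-bit
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def _check_axes(adj: AdjacencyMatrix, drug_sim: SimilarityMatrix | None,
                se_sim: SimilarityMatrix | None) -> None:
    if drug_sim is not None:
        if drug_sim.axis != Axis.DRUG:
            raise ValueError(f"drug similarity has axis {drug_sim.axis}, expected drug")
        if drug_sim.vocab.terms != adj.drug_vocab.terms:
            raise ValueError("drug similarity vocabulary does not match adjacency")
    if se_sim is not None:
        if se_sim.axis != Axis.SIDE_EFFECT:
            raise ValueError(f"SE similarity has axis {se_sim.axis}, expected side_effect")
        if se_sim.vocab.terms != adj.se_vocab.terms:
            raise ValueError("SE similarity vocabulary does not match adjacency")


def sim_x(adj: AdjacencyMatrix, drug_sim: SimilarityMatrix,
          alpha: int, beta: int) -> tuple[float, bool]:
    """Max similarity of drug ``alpha`` to drugs known for SE ``beta``, excluding ``alpha``.

    Returns ``(value, empty_flag)``; value is 0 when the related set is empty
    after exclusion.
    """
    _check_axes(adj, drug_sim, None)
    related = related_drugs(adj, beta) - {alpha}
    if not related:
        return 0.0, True
    return float(max(drug_sim.S[alpha, i] for i in related)), False


def sim_y(adj: AdjacencyMatrix, se_sim: SimilarityMatrix,
          alpha: int, beta: int) -> tuple[float, bool]:
    """Max similarity of SE ``beta`` to side effects known for drug ``alpha``, excluding ``beta``."""
    _check_axes(adj, None, se_sim)
    related = related_side_effects(adj, alpha) - {beta}
    if not related:
        return 0.0, True
    return float(max(se_sim.S[beta, j] for j in related)), False


def relation_score(sim_x_val: float, sim_y_val: float) -> float:
    """Relation score: the product of the two similarity factors."""
    return sim_x_val * sim_y_val


def _max_over_related(S: np.ndarray, R_bool: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each (query row a, evidence column b): max over {i : R[i, b]}, i != a, of S[a, i].

    S is a square similarity over the query axis, R_bool maps evidence axis
    members to related sets. Returns (values, empty_mask) of shape
    (S rows, R columns). Self-exclusion is implemented by a -inf diagonal: the
    query index only ever appears in its own related set.
    """
    n_q = S.shape[0]
    n_e = R_bool.shape[1]
    S_excl = S.copy()
    np.fill_diagonal(S_excl, -np.inf)
    values = np.zeros((n_q, n_e))
    empty = np.zeros((n_q, n_e), dtype=bool)
    for b in range(n_e):
        idx = np.flatnonzero(R_bool[:, b])
        if idx.size == 0:
            empty[:, b] = True
            continue
        col = S_excl[:, idx].max(axis=1)
        gone = np.isneginf(col)  # only the query itself was related
        values[:, b] = np.where(gone, 0.0, col)
        empty[:, b] = gone
    return values, empty


def score_all_pairs(adj: AdjacencyMatrix, drug_sim: SimilarityMatrix,
                    se_sim: SimilarityMatrix) -> ScoreMatrix:
    """Score every (drug, side effect) cell of the adjacency."""
    _check_axes(adj, drug_sim, se_sim)
    R_bool = adj.R.astype(bool)
    sx, ex = _max_over_related(drug_sim.S, R_bool)
    sy_t, ey_t = _max_over_related(se_sim.S, R_bool.T)
    sy, ey = sy_t.T, ey_t.T
    masked = ex | ey
    score = np.where(masked, 0.0, sx * sy)
    return ScoreMatrix(score=score, sim_x=sx, sim_y=sy,
                       empty_x_mask=ex, empty_y_mask=ey, adjacency=adj)


def top_novel_pairs(scores: ScoreMatrix, k: int) -> pd.DataFrame:
    """Top-``k`` highest-scoring pairs NOT in the known adjacency.

    Ties are broken by (drug term, side-effect term) lexicographic order for
    determinism. ``k`` larger than the number of unknown pairs returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frame = scores.to_long_frame()
    novel = frame[~frame["known"]].drop(columns="known")
    novel = novel.sort_values(["score", "drug", "side_effect"],
                              ascending=[False, True, True], kind="mergesort")
    return novel.head(k).reset_index(drop=True)


def pair_counts(n_drugs: int, n_ses: int) -> dict[str, int]:
    """Cell counts of a full run: within-axis similarity cells and scored pairs.

    Self-pairs are included in the similarity counts, matching full square
    matrices; exclusion is applied at scoring time, not when counting cells.
    """
    return {
        "drug_similarity_cells": n_drugs * n_drugs,
        "se_similarity_cells": n_ses * n_ses,
        "scored_pairs": n_drugs * n_ses,
    }
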