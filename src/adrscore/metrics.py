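"""Within-axis pairwise similarity matrices under five comparable metrics.

Cosine similarity is the primary metric:

    cos(A, B) = sum_i A_i B_i / (||A|| ||B||)

Alternatives kept for metric-comparison experiments: Euclidean and Manhattan
distances (converted to similarities by negation, which preserves ranking
order), generalized (Ruzicka) Jaccard on nonnegative vectors, and the raw dot
product. All matrices are full squares over the axis vocabulary, self-pairs
included; leave-one-out exclusion happens at scoring time, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise as _pw

from .embeddings import EmbeddingSet
from .relations import Axis, Vocabulary

__all__ = ["METRICS", "SimilarityMatrix", "cosine_similarity", "pairwise_similarity"]

METRICS = ("cosine", "euclidean", "manhattan", "jaccard", "dot")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square within-axis similarity matrix; higher always means closer.

    For ``cosine`` the diagonal is 1 and entries lie in [-1, 1]; for the
    negated distances the diagonal is 0 and off-diagonal entries are <= 0.
    """

    axis: Axis
    metric: str
    S: np.ndarray
    vocab: Vocabulary
    higher_is_closer: bool = True

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.float64)
        n = len(self.vocab)
        if S.shape != (n, n):
            raise ValueError(f"similarity matrix shape {S.shape} != ({n}, {n})")
        object.__setattr__(self, "S", S)

    @property
    def n_cells(self) -> int:
        n = len(self.vocab)
        return n * n

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.S, index=self.vocab.terms, columns=self.vocab.terms).to_csv(
            path, sep="\t", float_format="%.8g")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero-norm vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _ruzicka(X: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Generalized Jaccard sum(min)/sum(max) for rows of a nonnegative matrix."""
    n = X.shape[0]
    S = np.empty((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        mins = np.minimum(X[start:stop, None, :], X[None, :, :]).sum(axis=2)
        maxs = np.maximum(X[start:stop, None, :], X[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            S[start:stop] = np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 1.0)
    return S


def pairwise_similarity(
    emb: EmbeddingSet,
    metric: str = "cosine",
    vocab: Vocabulary | None = None,
    jaccard_min_shift: bool = False,
) -> SimilarityMatrix:
    """Compute the full square similarity matrix for one axis.

    ``jaccard_min_shift`` subtracts the global component minimum before the
    generalized Jaccard so embeddings with negative components can be compared;
    without it, negative components raise.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose one of {METRICS}")
    if vocab is None:
        vocab = Vocabulary.from_terms(emb.axis, emb.terms())
    X = emb.matrix(vocab)

    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = vocab.terms[int(np.argmin(norms))]
            raise ValueError(f"cosine similarity undefined: zero-norm vector for {bad!r}")
        S = np.clip(_pw.cosine_similarity(X), -1.0, 1.0)
        np.fill_diagonal(S, 1.0)
    elif metric == "euclidean":
        S = -_pw.euclidean_distances(X)
        np.fill_diagonal(S, 0.0)
    elif metric == "manhattan":
        S = -_pw.manhattan_distances(X)
        np.fill_diagonal(S, 0.0)
    elif metric == "dot":
        S = X @ X.T
    else:  # jaccard
        if jaccard_min_shift:
            X = X - min(X.min(), 0.0)
        if np.any(X < 0):
            raise ValueError(
                "generalized Jaccard requires nonnegative components; "
                "pass jaccard_min_shift=True to shift by the global minimum")
        S = _ruzicka(X)
    S = (S + S.T) / 2.0  # enforce exact symmetry against float round-off
    return SimilarityMatrix(axis=emb.axis, metric=metric, S=S, vocab=vocab)
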