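"""Planted-factor synthetic benchmark: relations, embeddings and an external extract.

Latent factors drive both the bipartite relation structure and the embedding
geometry, so the full pipeline can be exercised — and its parameter-recovery
behaviour measured — without any external data. Each drug and each side effect
is assigned one of ``n_factors`` latent factors uniformly at random; a relation
exists with probability ``p_in`` when the factors match and ``p_out``
otherwise. Embeddings are the factor's orthonormal centroid (the factor's row
of the identity basis, making the zero-noise geometry analytically checkable:
within-factor cosine exactly 1, cross-factor exactly 0) plus isotropic
Gaussian noise of standard deviation ``noise_sd``.

Entities that end up with zero relations are resampled until they have at
least one, matching the invariant of vocabularies induced from relation
tables. Term names are zero-padded so lexicographic vocabulary order equals
generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .relations import Axis, RelationTable
from .embeddings import EmbeddingSet
from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticData", "generate", "generate_external_extract"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's reference benchmark."""

    n_drugs: int = 60
    n_ses: int = 120
    n_factors: int = 6
    dim: int = 32
    p_in: float = 0.6
    p_out: float = 0.02
    noise_sd: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_ses < 1 or self.n_factors < 1:
            raise ValueError("n_drugs, n_ses and n_factors must be positive")
        if self.n_factors > min(self.n_drugs, self.n_ses):
            raise ValueError("n_factors must not exceed min(n_drugs, n_ses)")
        if self.dim < self.n_factors:
            raise ValueError("dim must be >= n_factors (orthonormal centroids)")
        if not (0.0 <= self.p_out <= 1.0 and 0.0 <= self.p_in <= 1.0):
            raise ValueError("p_in and p_out must be probabilities")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SyntheticData:
    relations: RelationTable
    drug_embeddings: EmbeddingSet
    se_embeddings: EmbeddingSet
    drug_factors: np.ndarray
    se_factors: np.ndarray
    n_resampled: int


def _drug_name(i: int) -> str:
    return f"drug{i:05d}"


def _se_name(j: int) -> str:
    return f"se{j:05d}"


def generate(cfg: SyntheticConfig) -> SyntheticData:
    """Draw one planted-factor dataset, deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_factors
    drug_f = rng.integers(0, K, size=cfg.n_drugs)
    se_f = rng.integers(0, K, size=cfg.n_ses)
    P = np.where(drug_f[:, None] == se_f[None, :], cfg.p_in, cfg.p_out)
    R = rng.random((cfg.n_drugs, cfg.n_ses)) < P

    # resample isolated entities so vocabularies induced from the pairs cover everyone
    n_resampled = 0
    for _ in range(1000):
        empty_rows = np.flatnonzero(~R.any(axis=1))
        for i in empty_rows:
            R[i] = rng.random(cfg.n_ses) < P[i]
            n_resampled += 1
        empty_cols = np.flatnonzero(~R.any(axis=0))
        for j in empty_cols:
            if P[:, j].max() == 0.0:
                # p_out = 0 and no drug shares this factor: reassign to a factor drugs have
                se_f[j] = rng.choice(np.unique(drug_f))
                P[:, j] = np.where(drug_f == se_f[j], cfg.p_in, cfg.p_out)
            R[:, j] = rng.random(cfg.n_drugs) < P[:, j]
            n_resampled += 1
        if R.any(axis=1).all() and R.any(axis=0).all():
            break
    else:
        raise RuntimeError("failed to eliminate isolated entities; raise p_in/p_out")
    if n_resampled:
        logger.info("resampled %d isolated rows/columns", n_resampled)

    centroids = np.eye(cfg.dim)[:K]
    drug_vecs = centroids[drug_f] + rng.normal(0.0, cfg.noise_sd, (cfg.n_drugs, cfg.dim))
    se_vecs = centroids[se_f] + rng.normal(0.0, cfg.noise_sd, (cfg.n_ses, cfg.dim))

    pairs = frozenset(
        (_drug_name(i), _se_name(j)) for i, j in zip(*np.nonzero(R))
    )
    relations = RelationTable(pairs=pairs, source_label=f"synthetic(seed={cfg.seed})")
    drug_emb = EmbeddingSet(
        axis=Axis.DRUG, dim=cfg.dim,
        vectors={_drug_name(i): drug_vecs[i] for i in range(cfg.n_drugs)},
        backend_label="synthetic")
    se_emb = EmbeddingSet(
        axis=Axis.SIDE_EFFECT, dim=cfg.dim,
        vectors={_se_name(j): se_vecs[j] for j in range(cfg.n_ses)},
        backend_label="synthetic")
    return SyntheticData(relations=relations, drug_embeddings=drug_emb,
                         se_embeddings=se_emb, drug_factors=drug_f, se_factors=se_f,
                         n_resampled=n_resampled)


def generate_external_extract(
    scores: ScoreMatrix,
    enrichment: float = 1.0,
    n_pairs: int = 200,
    seed: int = 0,
) -> RelationTable:
    """Sample a synthetic "external" known-relation set, optionally score-enriched.

    Cells are drawn without replacement with probability proportional to
    ``enrichment ** q`` where ``q`` is the cell's score rank quantile in [0, 1];
    ``enrichment = 1`` is uniform (a null external source), large values
    concentrate the extract on high-scoring pairs (a source that re-reports
    real signals).
    """
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1")
    n_cells = scores.score.size
    if not 1 <= n_pairs <= n_cells:
        raise ValueError(f"n_pairs must be in [1, {n_cells}]")
    rng = np.random.default_rng(seed)
    flat = scores.score.ravel()
    q = (rankdata(flat, method="average") - 1.0) / max(n_cells - 1, 1)
    weights = np.power(float(enrichment), q)
    probs = weights / weights.sum()
    chosen = rng.choice(n_cells, size=n_pairs, replace=False, p=probs)
    nd, ns = scores.shape
    drug_terms = scores.adjacency.drug_vocab.terms
    se_terms = scores.adjacency.se_vocab.terms
    pairs = frozenset(
        (drug_terms[idx // ns], se_terms[idx % ns]) for idx in chosen
    )
    return RelationTable(pairs=pairs,
                         source_label=f"synthetic_external(enrichment={enrichment},seed={seed})")
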