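"""Relation tables, term vocabularies and the drug x side-effect adjacency matrix.

A relation table is a set of (drug term, side-effect term) pairs, typically read
from a SIDER-style two-column TSV. The adjacency matrix ``R`` is the binary
|drugs| x |side effects| incidence matrix of those pairs; its row and column
vocabularies are induced from the observed pairs and sorted lexicographically so
every downstream matrix is reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.io import mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "Axis",
    "Vocabulary",
    "RelationTable",
    "AdjacencyMatrix",
    "read_relation_table",
    "build_adjacency",
    "related_drugs",
    "related_side_effects",
    "write_adjacency",
]


class Axis(str, Enum):
    DRUG = "drug"
    SIDE_EFFECT = "side_effect"


def normalize_term(term: str) -> str:
    """Case-fold and trim a raw term (the desk-scale stand-in for identifier mapping)."""
    return term.strip().lower()


@dataclass(frozen=True)
class Vocabulary:
    """Ordered, unique term list for one axis with a term -> 0-based index map."""

    axis: Axis
    terms: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ValueError("vocabulary must contain at least one term")
        if any(not t for t in self.terms):
            raise ValueError("vocabulary terms must be nonempty strings")
        idx = {t: i for i, t in enumerate(self.terms)}
        if len(idx) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")
        object.__setattr__(self, "index", idx)

    @classmethod
    def from_terms(cls, axis: Axis | str, terms: Iterable[str], *, sort: bool = True) -> "Vocabulary":
        uniq = sorted(set(terms)) if sort else list(dict.fromkeys(terms))
        return cls(axis=Axis(axis), terms=tuple(uniq))

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass(frozen=True)
class RelationTable:
    """Deduplicated set of (drug term, side-effect term) pairs."""

    pairs: frozenset[tuple[str, str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for d, s in self.pairs:
            if not d or not s:
                raise ValueError(f"relation pair has an empty member: {(d, s)!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def drug_terms(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def se_terms(self) -> set[str]:
        return {s for _, s in self.pairs}


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary |drugs| x |side effects| matrix; R[i, j] = 1 iff the pair is known."""

    R: np.ndarray
    drug_vocab: Vocabulary
    se_vocab: Vocabulary

    def __post_init__(self) -> None:
        R = np.asarray(self.R)
        if R.ndim != 2:
            raise ValueError("R must be a 2-D matrix")
        if R.shape != (len(self.drug_vocab), len(self.se_vocab)):
            raise ValueError(
                f"R shape {R.shape} does not match vocabularies "
                f"({len(self.drug_vocab)}, {len(self.se_vocab)})"
            )
        if not np.isin(R, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "R", R.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.R.shape

    def n_known(self) -> int:
        return int(self.R.sum())

    def to_pairs(self) -> frozenset[tuple[str, str]]:
        ii, jj = np.nonzero(self.R)
        return frozenset(
            (self.drug_vocab.terms[i], self.se_vocab.terms[j]) for i, j in zip(ii, jj)
        )


def read_relation_table(
    path: str | Path,
    drug_col: int = 0,
    se_col: int = 1,
    normalize: bool = True,
    skip_header: bool = False,
    mapping: Mapping[str, str] | None = None,
    source_label: str | None = None,
) -> RelationTable:
    """Read a two-column relation TSV into a deduplicated :class:`RelationTable`.

    Parameters
    ----------
    drug_col, se_col
        0-based tab-separated column indices of the drug and side-effect terms.
    normalize
        Lowercase and strip surrounding whitespace from both terms.
    mapping
        Optional term -> canonical-term map applied after normalization,
        emulating synonym merging done upstream by identifier databases.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"relation table not found: {path}")
    need = max(drug_col, se_col) + 1
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise ValueError(
                    f"{path}:{lineno}: expected at least {need} tab-separated "
                    f"fields, found {len(fields)}"
                )
            drug, se = fields[drug_col], fields[se_col]
            if normalize:
                drug, se = normalize_term(drug), normalize_term(se)
            if mapping is not None:
                drug = mapping.get(drug, drug)
                se = mapping.get(se, se)
            if not drug or not se:
                raise ValueError(f"{path}:{lineno}: empty drug or side-effect term")
            pairs.add((drug, se))
            n_rows += 1
    if not pairs:
        raise ValueError(f"no relation pairs found in {path}")
    n_dup = n_rows - len(pairs)
    logger.info("read %d rows from %s: %d unique pairs, %d duplicates removed",
                n_rows, path, len(pairs), n_dup)
    return RelationTable(pairs=frozenset(pairs), source_label=source_label or str(path))


def build_adjacency(rel: RelationTable) -> AdjacencyMatrix:
    """Build the binary adjacency matrix with vocabularies induced from the pairs.

    Vocabularies are the lexicographically sorted unique drug and side-effect
    terms, so every row and column has at least one 1 and the total 1-count
    equals ``len(rel)``.
    """
    if len(rel) == 0:
        raise ValueError("relation table is empty")
    drug_vocab = Vocabulary.from_terms(Axis.DRUG, rel.drug_terms())
    se_vocab = Vocabulary.from_terms(Axis.SIDE_EFFECT, rel.se_terms())
    R = np.zeros((len(drug_vocab), len(se_vocab)), dtype=np.int8)
    for d, s in rel.pairs:
        R[drug_vocab.index[d], se_vocab.index[s]] = 1
    return AdjacencyMatrix(R=R, drug_vocab=drug_vocab, se_vocab=se_vocab)


def related_drugs(adj: AdjacencyMatrix, se_index: int) -> set[int]:
    """Indices of drugs known to be associated with side effect ``se_index``."""
    if not 0 <= se_index < len(adj.se_vocab):
        raise IndexError(f"side-effect index {se_index} out of range [0, {len(adj.se_vocab)})")
    return set(np.flatnonzero(adj.R[:, se_index]).tolist())


def related_side_effects(adj: AdjacencyMatrix, drug_index: int) -> set[int]:
    """Indices of side effects known to be associated with drug ``drug_index``."""
    if not 0 <= drug_index < len(adj.drug_vocab):
        raise IndexError(f"drug index {drug_index} out of range [0, {len(adj.drug_vocab)})")
    return set(np.flatnonzero(adj.R[drug_index, :]).tolist())


def write_adjacency(adj: AdjacencyMatrix, out_dir: str | Path, stem: str = "adjacency") -> None:
    """Export the adjacency as Matrix Market plus two plain-text vocabulary sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / f"{stem}.mtx"), sparse.coo_matrix(adj.R))
    (out_dir / f"{stem}.drugs.txt").write_text(
        "\n".join(adj.drug_vocab.terms) + "\n", encoding="utf-8")
    (out_dir / f"{stem}.side_effects.txt").write_text(
        "\n".join(adj.se_vocab.terms) + "\n", encoding="utf-8")
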