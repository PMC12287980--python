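"""External validation of predictions against an independent relation extract.

Predicted labels (score strictly above a threshold) are cross-tabulated with an
external pharmacovigilance extract (FAERS-style two-column pairs). Because
externally unknown pairs vastly outnumber known ones, each repeat takes all
externally known pairs plus an equal-size uniform sample of unknown pairs,
runs a two-sided Fisher exact test on the 2x2 table, and the repeats are
aggregated by arithmetic mean (median also reported, for robustness under
skewed per-repeat odds ratios).

Contingency-table orientation: rows are externally known vs unknown pair,
columns are predicted related vs not. Odds ratio is the cross-product
(a*d)/(b*c); when any cell is zero the Haldane-Anscombe +0.5 correction is
applied to all four cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .relations import RelationTable, Vocabulary
from .scoring import ScoreMatrix

__all__ = ["ContingencyTable", "ValidationResult", "predict_labels",
           "odds_ratio", "balanced_fisher_validation"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = known & predicted, b = known & not, c = unknown & predicted, d = unknown & not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class ValidationResult:
    """Aggregated balanced-resampling Fisher validation over ``n_repeats`` repeats."""

    n_repeats: int
    mean_p: float
    mean_or: float
    median_p: float
    median_or: float
    per_repeat: tuple[tuple[float, float], ...]  # (p, odds ratio) per repeat
    seed: int

    def to_report(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "mean_p": self.mean_p,
            "mean_odds_ratio": self.mean_or,
            "median_p": self.median_p,
            "median_odds_ratio": self.median_or,
            "seed": self.seed,
        }


def predict_labels(scores: ScoreMatrix | np.ndarray, threshold: float) -> np.ndarray:
    """Binary predictions: a pair is predicted related iff its score exceeds the threshold.

    The inequality is strict, so a score exactly at the threshold is predicted
    NOT related.
    """
    arr = scores.score if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    return (arr > threshold).astype(np.int8)


def odds_ratio(t: ContingencyTable) -> float:
    """Cross-product odds ratio with Haldane-Anscombe +0.5 on any zero cell."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _external_mask(external: RelationTable, drug_vocab: Vocabulary,
                   se_vocab: Vocabulary) -> np.ndarray:
    mask = np.zeros((len(drug_vocab), len(se_vocab)), dtype=bool)
    n_outside = 0
    for d, s in external.pairs:
        i = drug_vocab.index.get(d)
        j = se_vocab.index.get(s)
        if i is None or j is None:
            n_outside += 1
            continue
        mask[i, j] = True
    return mask


def balanced_fisher_validation(
    predictions: np.ndarray,
    external: RelationTable,
    drug_vocab: Vocabulary,
    se_vocab: Vocabulary,
    n_repeats: int = 2000,
    seed: int = 0,
) -> ValidationResult:
    """Repeated balanced Fisher exact test of predictions vs an external extract.

    Each repeat pairs ALL externally known pairs with an equal-size sample of
    externally unknown pairs, drawn uniformly without replacement from an
    independent substream of the seeded generator, so the result is fully
    reproducible from ``seed``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    predictions = np.asarray(predictions)
    if predictions.shape != (len(drug_vocab), len(se_vocab)):
        raise ValueError("prediction matrix shape does not match the vocabularies")
    known_mask = _external_mask(external, drug_vocab, se_vocab)
    known_idx = np.flatnonzero(known_mask.ravel())
    unknown_idx = np.flatnonzero(~known_mask.ravel())
    if known_idx.size == 0:
        raise ValueError("external relation set is empty within the vocabularies")
    if unknown_idx.size < known_idx.size:
        raise ValueError(
            f"only {unknown_idx.size} externally unknown pairs available, "
            f"need at least {known_idx.size} for balanced sampling")

    pred_flat = predictions.ravel().astype(bool)
    n_known = known_idx.size
    a = int(pred_flat[known_idx].sum())  # constant across repeats
    b = n_known - a

    streams = np.random.SeedSequence(seed).spawn(n_repeats)
    per_repeat: list[tuple[float, float]] = []
    for child in streams:
        rng = np.random.default_rng(child)
        sample = rng.choice(unknown_idx, size=n_known, replace=False)
        c = int(pred_flat[sample].sum())
        d = n_known - c
        table = ContingencyTable(a, b, c, d)
        p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
        per_repeat.append((p, odds_ratio(table)))

    ps = np.array([p for p, _ in per_repeat])
    ors = np.array([o for _, o in per_repeat])
    return ValidationResult(
        n_repeats=n_repeats,
        mean_p=float(ps.mean()),
        mean_or=float(ors.mean()),
        median_p=float(np.median(ps)),
        median_or=float(np.median(ors)),
        per_repeat=tuple(per_repeat),
        seed=seed,
    )
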