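"""Term embedding vectors for one axis, from files, an encoder, or synthesis.

The canonical exchange format is the word2vec text dialect: an optional
``count dim`` header line, then one line per term with the term followed by
``dim`` floats. Multi-word biomedical terms ("acute pulmonary edema") are
supported by taking the last ``dim`` whitespace tokens of a line as the vector
and everything before them as the term.
"""

from __future__ import annotations

import importlib.util
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np

from .relations import Axis, Vocabulary

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingSet", "load_word_vectors", "write_word_vectors", "encode_terms"]


@dataclass(frozen=True)
class EmbeddingSet:
    """Fixed-dimension term -> vector map for one axis."""

    axis: Axis
    dim: int
    vectors: Mapping[str, np.ndarray]
    backend_label: str = ""
    allow_zero: bool = False

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        vecs = {}
        for term, v in self.vectors.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.dim,):
                raise ValueError(
                    f"vector for {term!r} has shape {v.shape}, expected ({self.dim},)")
            if not self.allow_zero and not np.any(v):
                raise ValueError(f"vector for {term!r} is all-zero (pass allow_zero=True to permit)")
            vecs[term] = v
        object.__setattr__(self, "vectors", vecs)

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def terms(self) -> list[str]:
        return sorted(self.vectors)

    def coverage(self, vocab: Vocabulary) -> tuple[list[str], list[str]]:
        """Partition a vocabulary into (covered, missing) term lists."""
        covered = [t for t in vocab.terms if t in self.vectors]
        missing = [t for t in vocab.terms if t not in self.vectors]
        return covered, missing

    def matrix(self, vocab: Vocabulary) -> np.ndarray:
        """Stack vectors in vocabulary order into a |vocab| x dim array."""
        missing = [t for t in vocab.terms if t not in self.vectors]
        if missing:
            raise KeyError(
                f"{len(missing)} vocabulary terms lack vectors, e.g. {missing[:3]}")
        return np.stack([self.vectors[t] for t in vocab.terms])


def _parse_header(line: str) -> tuple[int, int] | None:
    toks = line.split()
    if len(toks) == 2:
        try:
            return int(toks[0]), int(toks[1])
        except ValueError:
            return None
    return None


def load_word_vectors(
    path: str | Path,
    vocab: Vocabulary | None = None,
    on_missing: Literal["error", "skip", "zero"] = "error",
    axis: Axis | str | None = None,
) -> EmbeddingSet:
    """Load word2vec-text-format vectors, optionally restricted to a vocabulary.

    ``on_missing`` governs vocabulary terms absent from the file: ``error``
    (default; silent zeros would corrupt similarity ranks), ``skip`` (drop the
    term with a warning), or ``zero`` (explicit zero vector).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"word-vector file not found: {path}")
    if axis is None:
        axis = vocab.axis if vocab is not None else Axis.DRUG
    axis = Axis(axis)
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        header = _parse_header(first)
        lines = enumerate(fh, start=2)
        if header is not None:
            dim = header[1]
        else:
            lines = [(1, first)] + list(lines)  # type: ignore[assignment]
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split()
            if dim is None:
                # infer dim from the trailing float-parsable tokens of the first row
                n_float = 0
                for tok in reversed(toks):
                    try:
                        float(tok)
                        n_float += 1
                    except ValueError:
                        break
                if n_float == 0:
                    raise ValueError(f"{path}:{lineno}: no numeric fields")
                dim = n_float
            if len(toks) <= dim:
                raise ValueError(
                    f"{path}:{lineno}: expected a term plus {dim} floats, got {len(toks)} tokens")
            term = " ".join(toks[:-dim])
            try:
                vec = np.array([float(t) for t in toks[-dim:]], dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric vector component") from exc
            vectors[term] = vec
    if dim is None or not vectors:
        raise ValueError(f"no vectors found in {path}")

    if vocab is not None:
        covered = {t: vectors[t] for t in vocab.terms if t in vectors}
        missing = [t for t in vocab.terms if t not in vectors]
        if missing:
            if on_missing == "error":
                raise KeyError(
                    f"{len(missing)} vocabulary terms missing from {path}, "
                    f"first: {missing[0]!r}")
            if on_missing == "zero":
                for t in missing:
                    covered[t] = np.zeros(dim)
            logger.warning("%d of %d vocabulary terms missing from %s (policy=%s)",
                           len(missing), len(vocab), path, on_missing)
        logger.info("coverage: %d covered + %d missing = %d vocabulary terms",
                    len(vocab) - len(missing), len(missing), len(vocab))
        vectors = covered
    return EmbeddingSet(axis=axis, dim=dim, vectors=vectors,
                        backend_label=f"file:{path.name}",
                        allow_zero=(on_missing == "zero"))


def write_word_vectors(emb: EmbeddingSet, path: str | Path) -> None:
    """Write vectors in word2vec text format (with a ``count dim`` header).

    Components are printed with 17 significant digits, which round-trips IEEE
    doubles exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(emb)} {emb.dim}\n")
        for term in emb.terms():
            vals = " ".join(f"{x:.17g}" for x in emb.vectors[term])
            fh.write(f"{term} {vals}\n")


def _backend_available() -> bool:
    return (importlib.util.find_spec("transformers") is not None
            and importlib.util.find_spec("torch") is not None)


def encode_terms(
    terms: Iterable[str],
    encoder_id: str,
    pooling: Literal["mean_tokens", "first_token"] = "mean_tokens",
    layer: Literal["last_hidden"] = "last_hidden",
    axis: Axis | str = Axis.DRUG,
) -> EmbeddingSet:
    """Embed each term independently with a local contextual encoder.

    Each term is encoded context-free as its own sequence; ``mean_tokens``
    averages final-hidden-layer token vectors excluding special tokens (the
    standard context-free term-embedding choice, symmetric in token order),
    ``first_token`` takes the [CLS]-position vector. Deterministic given the
    encoder weights (evaluation mode, no dropout).

    The backend is optional: when the encoder stack is not installed locally
    this raises rather than attempting any download, so the core pipeline never
    needs network access.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("terms must be nonempty")
    if layer != "last_hidden":
        raise ValueError(f"unsupported layer {layer!r}; only 'last_hidden' is implemented")
    if pooling not in ("mean_tokens", "first_token"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if not _backend_available():
        raise RuntimeError(
            f"encoder backend for {encoder_id!r} is unavailable (transformers/torch "
            "not installed); precompute vectors and use load_word_vectors instead")

    import torch
    from transformers import AutoModel, AutoTokenizer

    tokenizer = AutoTokenizer.from_pretrained(encoder_id)
    model = AutoModel.from_pretrained(encoder_id)
    model.eval()
    vectors: dict[str, np.ndarray] = {}
    with torch.no_grad():
        for term in terms:
            enc = tokenizer(term, return_tensors="pt")
            hidden = model(**enc).last_hidden_state[0]  # (n_tokens, dim)
            if pooling == "first_token":
                vec = hidden[0]
            else:
                special = tokenizer.get_special_tokens_mask(
                    enc["input_ids"][0].tolist(), already_has_special_tokens=True)
                keep = torch.tensor([m == 0 for m in special])
                vec = hidden[keep].mean(dim=0) if keep.any() else hidden.mean(dim=0)
            vectors[term] = vec.numpy().astype(np.float64)
    dim = next(iter(vectors.values())).shape[0]
    return EmbeddingSet(axis=Axis(axis), dim=dim, vectors=vectors,
                        backend_label=f"encoder:{encoder_id}:{pooling}")
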