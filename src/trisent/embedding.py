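"""Word-embedding providers and mean-pooled document vectors.

A provider maps tokens to fixed-dimension real vectors (default d = 20,
matching the pretrained embedding the scoring models were designed
around).  Document vectors are the arithmetic mean of token vectors, so
they are permutation-invariant; an empty token stream maps to the zero
vector.

Two providers are included:

* :class:`HashEmbedding` — fully offline and deterministic: each token's
  vector is drawn from an RNG seeded by a stable hash of (seed, token).
  When a ``polarity_axis`` and a lexicon are supplied, tokens from the
  positive/negative/neutral lexicons receive +1/-1/0 on that coordinate,
  giving regressors a learnable polarity signal.
* :class:`TableEmbedding` — an adapter for real pretrained vectors stored
  as TSV (token followed by d reals per line); out-of-vocabulary tokens
  fall back to the zero vector.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np

from .synthetic_data import LexiconConfig
from .text_prep import TokenStream

DEFAULT_DIMENSION = 20


class EmbeddingProvider(Protocol):
    """Contract every embedding backend satisfies."""

    dimension: int
    name: str

    def vector(self, token: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


def _stable_token_seed(seed: int, token: str) -> int:
    digest = hashlib.blake2b(f"{seed}\x00{token}".encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**63)


class HashEmbedding:
    """Deterministic per-token Gaussian vectors seeded by a token hash."""

    def __init__(
        self,
        dimension: int = DEFAULT_DIMENSION,
        seed: int = 0,
        scale: float = 0.3,
        polarity_axis: int | None = None,
        lexicon: LexiconConfig | None = None,
    ):
        if dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {dimension}")
        if polarity_axis is not None and not 0 <= polarity_axis < dimension:
            raise ValueError(
                f"polarity_axis {polarity_axis} out of range for dimension {dimension}"
            )
        self.dimension = dimension
        self.seed = seed
        self.scale = scale
        self.polarity_axis = polarity_axis
        self.name = f"hash-d{dimension}-s{seed}"
        self._polarity: dict[str, float] = {}
        if polarity_axis is not None and lexicon is not None:
            for t in lexicon.positive_terms:
                self._polarity[t] = 1.0
            for t in lexicon.negative_terms:
                self._polarity[t] = -1.0
            for t in lexicon.neutral_terms:
                self._polarity[t] = 0.0

    def vector(self, token: str) -> np.ndarray:
        rng = np.random.default_rng(_stable_token_seed(self.seed, token))
        vec = rng.normal(0.0, self.scale, size=self.dimension)
        if self.polarity_axis is not None and token in self._polarity:
            vec[self.polarity_axis] = self._polarity[token]
        return vec


class TableEmbedding:
    """Pretrained vectors from a TSV file: ``token \\t v1 ... vd`` per line."""

    def __init__(self, table: dict[str, np.ndarray], dimension: int, name: str = "table"):
        self.table = table
        self.dimension = dimension
        self.name = name
        self._fallback = np.zeros(dimension)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableEmbedding":
        table: dict[str, np.ndarray] = {}
        dimension: int | None = None
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            token, values = parts[0], np.asarray([float(x) for x in parts[1:]])
            if dimension is None:
                dimension = values.size
            elif values.size != dimension:
                raise ValueError(
                    f"inconsistent embedding dimension for token {token!r}: "
                    f"{values.size} != {dimension}"
                )
            table[token] = values
        if dimension is None:
            raise ValueError("embedding TSV is empty")
        return cls(table, dimension, name=f"table:{Path(path).name}")

    def vector(self, token: str) -> np.ndarray:
        return self.table.get(token, self._fallback)


def embed_document(tokens: TokenStream | Iterable[str], provider: EmbeddingProvider) -> np.ndarray:
    """Mean-pool token vectors into one document vector.

    The empty stream maps to the zero vector of the provider's dimension.
    """
    toks = list(tokens)
    if not toks:
        return np.zeros(provider.dimension)
    return np.mean([provider.vector(t) for t in toks], axis=0)


def embed_corpus(streams: Iterable[TokenStream | Iterable[str]], provider: EmbeddingProvider) -> np.ndarray:
    """Stack document vectors for a corpus into an (n, d) matrix."""
    vecs = [embed_document(s, provider) for s in streams]
    if not vecs:
        return np.zeros((0, provider.dimension))
    return np.vstack(vecs)
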