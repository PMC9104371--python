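"""Text normalisation, tokenisation and stop-word removal.

Tokenisation is deliberately simple and reproducible: Unicode-aware
lowercasing, extraction of alphabetic word tokens (punctuation and digits
are dropped), then stop-word filtering.  The survey texts this pipeline
targets were machine-translated before scoring; that step is modelled as a
pluggable ``transform`` (string -> string) whose default is the identity,
so the whole pipeline runs offline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

# Alphabetic runs only: digits, punctuation and underscores are separators.
_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


@dataclass(frozen=True)
class TokenStream:
    """An ordered sequence of lowercase word tokens from one document."""

    tokens: tuple[str, ...]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def as_text(self) -> str:
        return " ".join(self.tokens)


def tokenize(text: str) -> list[str]:
    """Lowercase ``text`` and return its alphabetic word tokens in order."""
    return _WORD_RE.findall(text.casefold())


def preprocess(text: str, stopwords: Iterable[str] = (), source_id: str = "") -> TokenStream:
    """Normalise ``text`` into a :class:`TokenStream` with stop words removed.

    Total on strings: the empty string (or a string of pure punctuation)
    yields an empty stream.  Idempotent when re-applied to its own output
    rendered back to text.
    """
    stop = frozenset(stopwords) if not isinstance(stopwords, frozenset) else stopwords
    tokens = tuple(t for t in tokenize(text) if t not in stop)
    return TokenStream(tokens=tokens, source_id=source_id)


class TransformError(RuntimeError):
    """A text transform failed for a specific document."""

    def __init__(self, source_id: str, cause: Exception):
        super().__init__(f"text transform failed for document {source_id!r}: {cause}")
        self.source_id = source_id
        self.cause = cause


def identity_transform(text: str) -> str:
    return text


def transform_text(
    text: str,
    transform: Callable[[str], str] = identity_transform,
    source_id: str = "",
) -> str:
    """Apply a total string->string transform (translation slot) to ``text``.

    Failures are wrapped in :class:`TransformError` carrying the document id
    so a pipeline run can report which testimony broke.
    """
    try:
        return transform(text)
    except Exception as exc:  # noqa: BLE001 - contract: propagate with id
        raise TransformError(source_id, exc) from exc


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word file: one token per line, ``#`` comments, blank lines ignored."""
    words: set[str] = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            words.add(line.casefold())
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """The packaged default English stop-word list."""
    text = resources.files("trisent.data").joinpath("stopwords_en.txt").read_text("utf-8")
    words = set()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            words.add(line.casefold())
    return frozenset(words)
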