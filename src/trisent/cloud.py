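"""Frequency-thresholded term statistics and word-cloud rendering.

Counts are raw corpus-wide occurrence tallies after preprocessing (stop
words removed); only terms repeated at least ``min_count`` times (default
20) enter the table.  Rendering uses a small deterministic layout engine:
words are placed largest-first on an Archimedean spiral from the image
centre, with rectangle collision tests, and the font size is directly
proportional to the term count.  Given the same table and seed the layout
metadata is identical, which makes the rendering testable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthetic_data import Testimony
from .text_prep import preprocess

DEFAULT_MIN_COUNT = 20


@dataclass(frozen=True)
class TermFrequencyTable:
    """token -> corpus-wide count, restricted to count >= min_count."""

    entries: dict[str, int]
    min_count: int

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def top(self, k: int | None = None) -> list[tuple[str, int]]:
        """Terms sorted by count descending, alphabetical tie-break."""
        ranked = sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked if k is None else ranked[:k]

    def normalized(self) -> dict[str, float]:
        """Counts as relative frequencies of the retained terms."""
        total = sum(self.entries.values())
        return {t: c / total for t, c in self.entries.items()} if total else {}


def term_frequencies(
    corpus: Sequence[Testimony] | Iterable[str],
    stopwords: Iterable[str] = (),
    min_count: int = DEFAULT_MIN_COUNT,
) -> TermFrequencyTable:
    """Tally token occurrences over the corpus, keeping counts >= min_count.

    Accepts testimonies or raw strings.  Raising ``min_count`` can only
    shrink the table (anti-monotone filter).
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    stop = frozenset(stopwords)
    counter: Counter[str] = Counter()
    for doc in corpus:
        text = doc.text if isinstance(doc, Testimony) else doc
        counter.update(preprocess(text, stop).tokens)
    return TermFrequencyTable(
        entries={t: c for t, c in counter.items() if c >= min_count},
        min_count=min_count,
    )


@dataclass(frozen=True)
class PlacedWord:
    token: str
    count: int
    font_size: float  # points; proportional to count
    x: float  # centre coordinates in pixels
    y: float


@dataclass(frozen=True)
class CloudLayout:
    words: tuple[PlacedWord, ...]
    width: int
    height: int
    seed: int


def _estimate_box(token: str, font_size: float) -> tuple[float, float]:
    # crude but monotone glyph metrics: ~0.6 em advance per character
    return 0.62 * font_size * len(token) + 4.0, 1.25 * font_size + 4.0


def _overlaps(box, others) -> bool:
    x, y, w, h = box
    for ox, oy, ow, oh in others:
        if abs(x - ox) < (w + ow) / 2 and abs(y - oy) < (h + oh) / 2:
            return True
    return False


def layout_cloud(
    table: TermFrequencyTable,
    width: int = 800,
    height: int = 400,
    max_font_size: float = 72.0,
    seed: int = 0,
) -> CloudLayout:
    """Place words largest-first on a spiral; deterministic under seed."""
    if not table.entries:
        raise ValueError("cannot lay out an empty term-frequency table")
    rng = np.random.default_rng(seed)
    ranked = table.top()
    max_count = ranked[0][1]
    placed: list[PlacedWord] = []
    boxes: list[tuple[float, float, float, float]] = []
    cx, cy = width / 2.0, height / 2.0
    for token, count in ranked:
        size = max_font_size * count / max_count
        w, h = _estimate_box(token, size)
        theta0 = float(rng.uniform(0.0, 2.0 * np.pi))
        position = None
        max_r = float(np.hypot(width, height))
        for step in range(4000):
            r = max_r * step / 4000.0
            theta = theta0 + 0.5 * np.sqrt(step)
            x = cx + r * np.cos(theta)
            y = cy + r * np.sin(theta)
            if not (w / 2 <= x <= width - w / 2 and h / 2 <= y <= height - h / 2):
                continue
            if not _overlaps((x, y, w, h), boxes):
                position = (x, y)
                break
        if position is None:
            # deterministic fallback: scan a coarse grid outward from centre
            xs = np.arange(w / 2, width - w / 2 + 1e-9, 10.0)
            ys = np.arange(h / 2, height - h / 2 + 1e-9, 10.0)
            candidates = [(x, y) for x in xs for y in ys]
            candidates.sort(key=lambda p: (p[0] - cx) ** 2 + (p[1] - cy) ** 2)
            for x, y in candidates:
                if not _overlaps((x, y, w, h), boxes):
                    position = (x, y)
                    break
        if position is None:
            continue  # genuinely no room left for this (small) word
        boxes.append((position[0], position[1], w, h))
        placed.append(PlacedWord(token=token, count=count, font_size=size, x=position[0], y=position[1]))
    return CloudLayout(words=tuple(placed), width=width, height=height, seed=seed)


def render_cloud(
    table: TermFrequencyTable,
    out_path: str | Path,
    width: int = 800,
    height: int = 400,
    max_font_size: float = 72.0,
    seed: int = 0,
) -> CloudLayout:
    """Render the table to a PNG and return the layout metadata."""
    layout = layout_cloud(table, width=width, height=height, max_font_size=max_font_size, seed=seed)
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    dpi = 100
    fig = plt.figure(figsize=(width / dpi, height / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, width)
    ax.set_ylim(0, height)
    ax.axis("off")
    rng = np.random.default_rng(layout.seed)
    cmap = plt.get_cmap("viridis")
    for word in layout.words:
        ax.text(
            word.x,
            word.y,
            word.token,
            fontsize=word.font_size,
            ha="center",
            va="center",
            color=cmap(float(rng.uniform(0.0, 0.85))),
        )
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return layout


def table_to_tsv(table: TermFrequencyTable, path: str | Path) -> None:
    lines = [f"{token}\t{count}" for token, count in table.top()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def table_from_tsv(path: str | Path, min_count: int = 1) -> TermFrequencyTable:
    entries: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            token, count = line.split("\t")
            entries[token] = int(count)
    return TermFrequencyTable(entries=entries, min_count=min_count)
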