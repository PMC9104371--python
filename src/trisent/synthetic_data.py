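"""Synthetic survey and binary-polarity corpora.

Real lockdown-survey testimonies cannot be redistributed, so this module
synthesises class-separable free text from class-conditional lexicons: each
document of gold class *c* draws most of its tokens from the class-*c*
lexicon (controlled by ``polarity_purity``), a fraction from a neutral
filler vocabulary (``noise_rate``), and the remainder from the competing
class lexicons.  This preserves the one statistical property the scoring
pipeline relies on — class-separable token usage — without any data access.

The default survey strata reproduce the study conditions this pipeline
models: 225 student and 140 staff responses from two countries with a
fixed per-country class breakdown, and a binary movie-review-style corpus
split 80/20 into train and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .labels import CLASSES, NEGATIVE, NEUTRAL, POSITIVE, validate_label

STUDENT = "student"
STAFF = "staff"


@dataclass(frozen=True)
class StratumSpec:
    """Class counts for one (country, role) survey stratum."""

    country: str
    role: str
    n_negative: int
    n_neutral: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.role not in (STUDENT, STAFF):
            raise ValueError(f"role must be {STUDENT!r} or {STAFF!r}, got {self.role!r}")
        for name in ("n_negative", "n_neutral", "n_positive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    @property
    def total(self) -> int:
        return self.n_negative + self.n_neutral + self.n_positive

    def count(self, label: str) -> int:
        return {NEGATIVE: self.n_negative, NEUTRAL: self.n_neutral, POSITIVE: self.n_positive}[
            validate_label(label)
        ]


#: Default strata: the per-country, per-role hand-label counts of the survey
#: this pipeline emulates (students: Spain 88/6/12, Colombia 84/26/9; staff:
#: Spain 41/14/27, Colombia 30/14/14; totals 225 students + 140 staff).
STUDY_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("Spain", STUDENT, 88, 6, 12),
    StratumSpec("Colombia", STUDENT, 84, 26, 9),
    StratumSpec("Spain", STAFF, 41, 14, 27),
    StratumSpec("Colombia", STAFF, 30, 14, 14),
)


@dataclass(frozen=True)
class LexiconConfig:
    """Vocabulary and sampling knobs for the synthetic text generator.

    ``polarity_purity`` is the probability that a non-filler token comes
    from the document's own class lexicon; ``noise_rate`` the probability
    that a token is neutral filler.  Both in [0, 1].
    """

    positive_terms: tuple[str, ...]
    negative_terms: tuple[str, ...]
    neutral_terms: tuple[str, ...]
    filler_terms: tuple[str, ...]
    doc_length_range: tuple[int, int] = (8, 30)
    polarity_purity: float = 0.9
    noise_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        pos, neg, neu = set(self.positive_terms), set(self.negative_terms), set(self.neutral_terms)
        if pos & neg or pos & neu or neg & neu:
            raise ValueError("class lexicons must be pairwise disjoint")
        if set(self.filler_terms) & (pos | neg | neu):
            raise ValueError("filler vocabulary must not overlap the class lexicons")
        lo, hi = self.doc_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"doc_length_range must satisfy 1 <= lo <= hi, got {self.doc_length_range}")
        if not 0.0 <= self.polarity_purity <= 1.0:
            raise ValueError("polarity_purity must lie in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")

    def class_terms(self, label: str) -> tuple[str, ...]:
        return {
            NEGATIVE: self.negative_terms,
            NEUTRAL: self.neutral_terms,
            POSITIVE: self.positive_terms,
        }[validate_label(label)]


def default_lexicon(**overrides) -> LexiconConfig:
    """Lockdown-survey themed lexicons with sensible generator defaults."""
    positive = (
        "grateful", "hope", "hopeful", "calm", "enjoy", "enjoyed", "appreciate",
        "opportunity", "learning", "growth", "positive", "happy", "together",
        "support", "supportive", "helpful", "reflection", "peaceful", "value",
        "valued", "closer", "healthy", "improve", "improved", "rest", "creativity",
        "productive", "thankful", "optimistic", "silver",
    )
    negative = (
        "anxiety", "anxious", "stress", "stressed", "fear", "afraid", "lonely",
        "loneliness", "uncertainty", "worried", "worry", "overwhelmed", "tired",
        "exhausted", "isolation", "isolated", "sad", "sadness", "depressed",
        "frustration", "frustrated", "difficult", "hard", "struggle", "struggling",
        "insomnia", "helpless", "precarious", "unemployment", "grief",
    )
    neutral = (
        "confinement", "lockdown", "pandemic", "university", "classes", "online",
        "home", "family", "people", "work", "working", "studying", "students",
        "teachers", "routine", "schedule", "screen", "internet", "house", "city",
        "government", "measures", "distance", "masks", "news", "situation",
        "quarantine", "teleworking", "exams", "semester",
    )
    filler = (
        "the", "and", "of", "to", "in", "that", "it", "is", "was", "for", "with",
        "have", "been", "this", "but", "not", "are", "my", "we", "our", "at",
        "day", "days", "time", "week", "month", "things", "way", "life", "now",
        "think", "feel", "felt", "know", "see", "going", "being", "much", "many",
        "also", "still", "some", "every", "other", "since", "during", "because",
    )
    params = dict(
        positive_terms=positive,
        negative_terms=negative,
        neutral_terms=neutral,
        filler_terms=filler,
    )
    params.update(overrides)
    return LexiconConfig(**params)


@dataclass(frozen=True)
class Testimony:
    """One free-text survey response with its stratum and optional gold label."""

    id: str
    text: str
    country: str
    role: str
    gold: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("testimony text must be non-empty")
        if self.gold is not None:
            validate_label(self.gold)


@dataclass(frozen=True)
class BinaryReview:
    """One binary-polarity training document (label 1 = positive)."""

    text: str
    label: int
    split: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.split not in ("train", "validation"):
            raise ValueError(f"split must be 'train' or 'validation', got {self.split!r}")


def _draw_tokens(rng: np.random.Generator, lexicon: LexiconConfig, label: str) -> list[str]:
    own = lexicon.class_terms(label)
    if not own:
        raise ValueError(f"empty lexicon for requested class {label!r}")
    others = tuple(
        t for other in CLASSES if other != label for t in lexicon.class_terms(other)
    )
    lo, hi = lexicon.doc_length_range
    length = int(rng.integers(lo, hi + 1))
    cut_noise = lexicon.noise_rate
    cut_own = cut_noise + (1.0 - cut_noise) * lexicon.polarity_purity
    tokens: list[str] = []
    for u in rng.random(length):
        if u < cut_noise and lexicon.filler_terms:
            pool = lexicon.filler_terms
        elif u < cut_own or not others:
            pool = own
        else:
            pool = others
        tokens.append(pool[int(rng.integers(len(pool)))])
    return tokens


def generate_survey_corpus(
    strata: Sequence[StratumSpec] = STUDY_STRATA,
    lexicon: LexiconConfig | None = None,
) -> list[Testimony]:
    """Generate a labeled survey corpus with exact per-stratum class counts.

    Deterministic under ``lexicon.seed``; the output order is a seeded
    shuffle so position carries no class information.
    """
    if not strata:
        raise ValueError("strata must be non-empty")
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(lexicon.seed)
    corpus: list[Testimony] = []
    for stratum in strata:
        i = 0
        for label in CLASSES:
            for _ in range(stratum.count(label)):
                text = " ".join(_draw_tokens(rng, lexicon, label))
                corpus.append(
                    Testimony(
                        id=f"{stratum.country.lower()}-{stratum.role}-{i:04d}",
                        text=text,
                        country=stratum.country,
                        role=stratum.role,
                        gold=label,
                    )
                )
                i += 1
    order = rng.permutation(len(corpus))
    return [corpus[j] for j in order]


def generate_binary_corpus(
    n: int,
    balance: float = 0.5,
    lexicon: LexiconConfig | None = None,
    split_ratio: float = 0.8,
) -> list[BinaryReview]:
    """Generate ``n`` binary-polarity reviews (label 1 drawn from the positive
    lexicon, label 0 from the negative one) with an 80/20-style split.

    ``balance`` is the fraction of label-1 documents; ``split_ratio`` the
    fraction assigned to the train split.  Reproducible under ``lexicon.seed``.
    """
    if n < 2:
        raise ValueError(f"n must be at least 2, got {n}")
    if not 0.0 < balance < 1.0:
        raise ValueError("balance must lie strictly between 0 and 1")
    if not 0.0 < split_ratio < 1.0:
        raise ValueError("split_ratio must lie strictly between 0 and 1")
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(np.random.SeedSequence([lexicon.seed, 1]))
    n_pos = int(round(n * balance))
    n_pos = min(max(n_pos, 1), n - 1)  # both labels always present
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n - n_pos, dtype=int)])
    labels = labels[rng.permutation(n)]
    n_train = int(round(n * split_ratio))
    reviews = []
    for i, label in enumerate(labels):
        cls = POSITIVE if label == 1 else NEGATIVE
        text = " ".join(_draw_tokens(rng, lexicon, cls))
        split = "train" if i < n_train else "validation"
        reviews.append(BinaryReview(text=text, label=int(label), split=split))
    return reviews


# ---------------------------------------------------------------------------
# Plain-text I/O

SURVEY_COLUMNS = ["id", "country", "role", "gold", "text"]
BINARY_COLUMNS = ["text", "label", "split"]


def write_survey_csv(corpus: Sequence[Testimony], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.id, t.country, t.role, t.gold or "", t.text) for t in corpus],
        columns=SURVEY_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_survey_csv(path: str | Path) -> list[Testimony]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        Testimony(
            id=str(r.id),
            text=str(r.text),
            country=str(r.country),
            role=str(r.role),
            gold=str(r.gold) or None,
        )
        for r in df.itertuples()
    ]


def write_binary_csv(corpus: Sequence[BinaryReview], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.text, r.label, r.split) for r in corpus], columns=BINARY_COLUMNS
    )
    df.to_csv(path, index=False)


def read_binary_csv(path: str | Path) -> list[BinaryReview]:
    df = pd.read_csv(path, keep_default_na=False)
    return [BinaryReview(text=str(r.text), label=int(r.label), split=str(r.split)) for r in df.itertuples()]


def strata_from_yaml(path: str | Path) -> list[StratumSpec]:
    """Load strata from YAML: a list of {country, role, negative, neutral, positive}."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return [
        StratumSpec(
            country=str(item["country"]),
            role=str(item["role"]),
            n_negative=int(item["negative"]),
            n_neutral=int(item["neutral"]),
            n_positive=int(item["positive"]),
        )
        for item in raw
    ]


def strata_to_yaml(strata: Sequence[StratumSpec], path: str | Path) -> None:
    payload = [
        {
            "country": s.country,
            "role": s.role,
            "negative": s.n_negative,
            "neutral": s.n_neutral,
            "positive": s.n_positive,
        }
        for s in strata
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
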