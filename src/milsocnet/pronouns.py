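"""Pronoun-category features: an open-lexicon stand-in for LIWC pronouns.

Each post is summarized by the fraction of its tokens falling in six
disjoint pronoun categories (first-person singular/plural, second person,
third-person singular/plural, impersonal) plus their sum as a
total-pronoun feature.  Fractions follow the LIWC "percentage of words"
convention.  These features distinguish self-reference ("i cant sleep")
from reference to others ("she has been struggling"), which is the signal
the anaphora-aware model variant consumes.

The lexicon ships as an editable plain-text resource; downstream code
reads the feature dimensionality from the extractor, never hard-codes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "PronounVector",
    "PronounLexicon",
    "load_default_lexicon",
    "extract_pronoun_features",
    "features_for_bag",
]

CATEGORIES = (
    "first_singular",
    "first_plural",
    "second",
    "third_singular",
    "third_plural",
    "impersonal",
)


@dataclass(frozen=True)
class PronounVector:
    first_singular: float
    first_plural: float
    second: float
    third_singular: float
    third_plural: float
    impersonal: float
    total: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.first_singular,
                self.first_plural,
                self.second,
                self.third_singular,
                self.third_plural,
                self.impersonal,
                self.total,
            ]
        )

    @property
    def dim(self) -> int:
        return 7


class PronounLexicon:
    """category -> word set; categories must be pairwise disjoint."""

    def __init__(self, categories: dict[str, set[str]]):
        if set(categories) != set(CATEGORIES):
            raise ValueError(f"lexicon must define exactly {CATEGORIES}")
        seen: dict[str, str] = {}
        for cat, words in categories.items():
            for w in words:
                if w in seen:
                    raise ValueError(f"{w!r} appears in both {seen[w]} and {cat}")
                seen[w] = cat
        self._word_to_cat = seen
        self.categories = {c: frozenset(ws) for c, ws in categories.items()}

    @classmethod
    def from_text(cls, text: str) -> "PronounLexicon":
        cats: dict[str, set[str]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, words = line.partition(":")
            cats[name.strip()] = set(words.split())
        return cls(cats)

    def category_of(self, token: str) -> str | None:
        return self._word_to_cat.get(token)


def load_default_lexicon() -> PronounLexicon:
    text = (
        resources.files("milsocnet")
        .joinpath("data/pronoun_lexicon.txt")
        .read_text(encoding="utf-8")
    )
    return PronounLexicon.from_text(text)


_DEFAULT: PronounLexicon | None = None


def _default() -> PronounLexicon:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_default_lexicon()
    return _DEFAULT


def extract_pronoun_features(
    tokens: Sequence[str], lexicon: PronounLexicon | None = None
) -> PronounVector:
    """Per-category token fractions; all-zero vector for an empty post.

    Counts are integers and the division happens once per category, so the
    total is exactly the sum of the six disjoint category fractions.
    """
    lex = lexicon or _default()
    counts = dict.fromkeys(CATEGORIES, 0)
    for tok in tokens:
        cat = lex.category_of(tok)
        if cat is not None:
            counts[cat] += 1
    n = len(tokens)
    if n == 0:
        return PronounVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    fracs = [counts[c] / n for c in CATEGORIES]
    return PronounVector(*fracs, total=sum(counts.values()) / n)


def features_for_bag(
    token_lists: Sequence[Sequence[str]],
    max_posts: int | None = None,
    lexicon: PronounLexicon | None = None,
) -> np.ndarray:
    """Stack per-post pronoun vectors; padded slots are all-zero rows.

    Returns an array of shape (max_posts or len(token_lists), 7).
    """
    n = len(token_lists) if max_posts is None else max_posts
    out = np.zeros((n, 7))
    for j, toks in enumerate(token_lists[:n]):
        out[j] = extract_pronoun_features(toks, lexicon).as_array()
    return out
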