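"""Text normalization, user filtering, tokenization and bag encoding.

The pipeline mirrors common practice for short social-media posts:

* rewrite @mentions to ``user``, URLs to ``url``, standalone numerals to
  ``number`` and ``#tag`` to ``hashtag tag``;
* drop users with fewer than 100 posts or less than 80% English posts
  (both bounds strict);
* lowercase, whitespace-tokenize and truncate each post to 55 tokens;
* keep each user's 2000 most recent posts and zero-pad shorter bags into a
  fixed (max_posts x max_tokens) id matrix with post- and token-level
  validity masks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .synthetic import Corpus, User

__all__ = [
    "normalize_text",
    "filter_users",
    "tokenize",
    "Vocabulary",
    "build_vocabulary",
    "TokenizedBag",
    "bag_encode",
    "encode_corpus",
]

PAD_ID = 0
OOV_ID = 1
PAD_TOKEN = "<pad>"
OOV_TOKEN = "<unk>"

# Patterns are anchored so rewriting is idempotent: an already-rewritten
# token ("user", "url", "number", "hashtag x") matches none of them.
_URL_RE = re.compile(r"(?:https?://\S+|(?<!\S)www\.\S+)")
_MENTION_RE = re.compile(r"(?<![\w@])@\w+")
_HASHTAG_RE = re.compile(r"(?<![\w#@])#(\w+)")
_NUMERAL_RE = re.compile(r"(?<!\S)\d+(?:[.,]\d+)*(?!\S)")


def normalize_text(raw: str) -> str:
    """Apply the four rewrite rules; total and idempotent."""
    text = _URL_RE.sub("url", raw)
    text = _MENTION_RE.sub("user", text)
    text = _HASHTAG_RE.sub(r"hashtag \1", text)
    text = _NUMERAL_RE.sub("number", text)
    return text


def default_english_predicate(post) -> bool:
    return bool(getattr(post, "is_english", True))


_COMMON_ENGLISH = {
    "the", "a", "an", "and", "or", "to", "of", "in", "on", "for", "is",
    "was", "are", "i", "you", "he", "she", "it", "we", "they", "my", "me",
    "with", "that", "this", "at", "so", "not", "have", "has", "be", "user",
    "url", "number", "hashtag",
}


def stopword_english_predicate(post, min_ratio: float = 0.15) -> bool:
    """Heuristic for corpora without language flags: share of very common
    English function words among the post's tokens."""
    tokens = tokenize(normalize_text(post.raw_text), max_tokens=10**9)
    if not tokens:
        return True
    hits = sum(1 for t in tokens if t in _COMMON_ENGLISH)
    return hits / len(tokens) >= min_ratio


def filter_users(
    corpus: Corpus,
    min_posts: int = 100,
    min_english_ratio: float = 0.8,
    english_predicate: Callable = default_english_predicate,
) -> Corpus:
    """Keep users with >= min_posts posts and >= min_english_ratio English
    posts; both removals are strict ('fewer than' / 'less than')."""
    kept: Corpus = []
    for user in corpus:
        if len(user.posts) < min_posts:
            continue
        n_english = sum(1 for p in user.posts if english_predicate(p))
        if n_english / len(user.posts) < min_english_ratio:
            continue
        kept.append(user)
    return kept


def tokenize(text: str, max_tokens: int = 55) -> list[str]:
    """Lowercased whitespace tokens, truncated to the first max_tokens."""
    return text.lower().split()[:max_tokens]


@dataclass
class Vocabulary:
    """token -> contiguous id map; id 0 is padding, id 1 the OOV token."""

    token_to_id: dict[str, int]

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, OOV_ID)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def id_to_token(self) -> list[str]:
        inv = [""] * len(self.token_to_id)
        for tok, i in self.token_to_id.items():
            inv[i] = tok
        return inv


def build_vocabulary(corpus: Corpus, max_size: Optional[int] = None) -> Vocabulary:
    """Frequency-ranked vocabulary over normalized, tokenized posts.

    Ties broken lexicographically so builds are deterministic.  max_size
    counts real tokens only (pad and OOV always present on top).
    """
    counts: dict[str, int] = {}
    for user in corpus:
        for post in user.posts:
            for tok in tokenize(normalize_text(post.raw_text), max_tokens=10**9):
                counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if max_size is not None:
        ranked = ranked[:max_size]
    mapping = {PAD_TOKEN: PAD_ID, OOV_TOKEN: OOV_ID}
    for tok, _ in ranked:
        mapping[tok] = len(mapping)
    return Vocabulary(mapping)


@dataclass
class TokenizedBag:
    """Fixed-shape encoding of one user's bag of posts."""

    token_ids: np.ndarray  # (max_posts, max_tokens) int
    post_mask: np.ndarray  # (max_posts,) {0,1}
    token_mask: np.ndarray  # (max_posts, max_tokens) {0,1}
    user_label: int
    tokens: list[list[str]]  # the kept posts' (truncated) token lists

    def __post_init__(self):
        assert (self.token_ids[self.token_mask == 0] == PAD_ID).all()


def bag_encode(
    user: User,
    vocab: Vocabulary,
    max_posts: int = 2000,
    max_tokens: int = 55,
) -> TokenizedBag:
    """Encode one user: most recent max_posts posts, zero-padded with masks.

    The timeline is ordered oldest-first, so "most recent" means the last
    max_posts elements.
    """
    if not user.posts:
        raise ValueError(f"user {user.user_id} has no posts; filter upstream")
    posts = user.posts[-max_posts:]
    ids = np.zeros((max_posts, max_tokens), dtype=np.int64)
    token_mask = np.zeros((max_posts, max_tokens), dtype=np.int64)
    post_mask = np.zeros(max_posts, dtype=np.int64)
    token_lists: list[list[str]] = []
    for j, post in enumerate(posts):
        toks = tokenize(normalize_text(post.raw_text), max_tokens=max_tokens)
        token_lists.append(toks)
        post_mask[j] = 1
        for k, tok in enumerate(toks):
            ids[j, k] = vocab[tok]
            token_mask[j, k] = 1
    return TokenizedBag(ids, post_mask, token_mask, user.label, token_lists)


def encode_corpus(
    corpus: Corpus,
    vocab: Vocabulary,
    max_posts: int = 2000,
    max_tokens: int = 55,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[TokenizedBag]]:
    """Stack every user's TokenizedBag into batch arrays.

    Returns (token_ids (U,P,T), token_mask, post_mask (U,P), labels (U,),
    bags) with users in corpus order.
    """
    bags = [bag_encode(u, vocab, max_posts, max_tokens) for u in corpus]
    ids = np.stack([b.token_ids for b in bags])
    tmask = np.stack([b.token_mask for b in bags])
    pmask = np.stack([b.post_mask for b in bags])
    labels = np.array([b.user_label for b in bags], dtype=np.int64)
    return ids, tmask, pmask, labels, bags
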