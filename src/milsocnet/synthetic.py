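"""Synthetic microblog corpus generator with known instance-level truth.

Real user-level mental-health corpora are built from self-declarations and
cannot be shared, so every downstream stage of this package is exercised on
generated bags instead.  A corpus is a list of users; each user is a bag of
short posts carrying a hidden instance label: posts drawn from a
"mental-health/self" topic (first-person pronouns over a health vocabulary)
are positive instances, while "mental-health/other" posts (the same health
vocabulary framed in the third person — a friend's or celebrity's
condition) and neutral-topic posts are negative.  The user's bag label is
the multiple-instance max rule over the hidden instance labels, which the
generator enforces by construction: users sampled as positive are redrawn
until they contain at least one self-health post, and controls are redrawn
until they contain none.

Generation is template-and-slot, not a language model: each post is a
pronoun slot plus topic-word slots plus optional noise words, with
mentions, URLs, numerals, hashtags and non-English posts injected at
configurable rates to exercise the preprocessing rules.  Identical
(config, seed) pairs yield byte-identical corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PostCountSpec",
    "DecorationRates",
    "GeneratorConfig",
    "Post",
    "User",
    "Corpus",
    "bag_label_oracle",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
]

HEALTH_SELF = "health_self"
HEALTH_OTHER = "health_other"
NEUTRAL = "neutral"

# Seed words for the mental-health topic; the remainder of each topic
# vocabulary is filled with generated tokens up to vocab_size_per_topic.
_HEALTH_SEED = [
    "depression", "anxiety", "therapy", "medication", "insomnia",
    "hopeless", "exhausted", "overwhelmed", "struggling", "diagnosed",
    "sad", "worthless", "crying", "numb", "panic",
]
_NEUTRAL_SEED = [
    "football", "coffee", "weather", "music", "holiday",
    "movie", "dinner", "weekend", "traffic", "garden",
    "project", "meeting", "recipe", "train", "beach",
]

# Template-and-slot generation.  {h} draws a health-topic word, {n} a
# neutral-topic word.  Health templates are SHARED between the self- and
# other-reference topics and carry two pronoun slots of the subject's
# person class ({a}, {b}) plus, in some templates, an incidental reference
# {r} to the opposite person class ("the anxiety makes ME so tired and SHE
# worries", "HER depression is back and I cant help").  Self posts fill
# {a}/{b} with first-person forms and {r} with third-person forms;
# other-reference posts do the opposite (sometimes using a proper name as
# the subject).  Neutral templates carry pronoun slots filled
# independently from a mixed pool.  Consequently no template n-gram and no
# single pronoun token separates self- from other-reference health posts:
# the signal is which person class *dominates* the post — exactly the
# quantity the per-post pronoun-category fractions summarize, and a
# structural property a word-level encoder must otherwise learn from the
# token sequence itself.
_HEALTH_TEMPLATES = [
    "{a} been feeling {h} since {b} missed the {n}",
    "{a} cant sleep and {b} {h} is back again",
    "{a} started {h} because {b} {h} got worse",
    "some days {a} just feel {h} and {b} hide away",
    "the {h} makes {a} so tired and {r} cant help",
    "{b} {h} is heavy and {a} skip the {n} now",
    "honestly {a} been {h} for weeks {r} said",
    "after the {n} the {h} hit {a} hard and {b} cry",
]
_DECLARATION_TEMPLATE = "i was diagnosed with depression"
_NEUTRAL_TEMPLATES = [
    "{q1} love the {n} on {n} nights with {q2}",
    "{q1} watched the {n} and {q2} liked the {n}",
    "cant believe {q1} missed the {n} {q2} wanted",
    "{q1} think the {n} needs more {n} for {q2}",
    "the {n} was great and {q1} enjoyed the {n}",
    "{q1} going to the {n} this {n} with {q2}",
    "{q1} said the {n} beats any {n} {q2} tried",
    "maybe {q1} will try the {n} after {q2} leaves",
]

# Slot fillers.  Pronoun forms come from the packaged lexicon; proper
# names stand in for third parties in a share of other-reference posts
# (a name scores zero in every pronoun category, as LIWC would).
_FIRST_PERSON = ["i", "im", "i'm", "i've", "me", "my", "mine", "myself"]
_THIRD_PERSON = ["she", "he", "her", "him", "his", "they", "them", "their",
                 "she's", "he's", "they're"]
_NAMES = ["john", "maria", "sam", "alexei", "tom", "lucy", "dave", "emma"]
_NEUTRAL_PRONOUNS = (_FIRST_PERSON + _THIRD_PERSON
                     + ["you", "your", "we", "us", "it", "this", "someone"])
_NAME_RATE = 0.3  # share of other-reference posts using a name as subject
_INCIDENTAL_RATE = 0.5  # share of {r} slots actually filled cross-person
_FOREIGN_TOKENS = [
    "zolki", "mardu", "velti", "anor", "sipra", "quen", "tolva", "brin",
    "eska", "lumo", "farn", "ditsu", "kavel", "ronto", "miel", "sov",
]
_SYLLABLES = ["ba", "do", "ki", "lu", "mo", "na", "pe", "ri", "su", "ta", "ve", "zo"]


@dataclass(frozen=True)
class PostCountSpec:
    """Distribution of posts per user: Poisson(mean) clipped to [min, max]."""

    min: int = 50
    max: int = 50
    mean: float = 50.0


@dataclass(frozen=True)
class DecorationRates:
    mention: float = 0.15
    url: float = 0.10
    numeral: float = 0.10
    hashtag: float = 0.10


@dataclass(frozen=True)
class GeneratorConfig:
    n_positive_users: int = 300
    n_control_users: int = 300
    posts_per_user: PostCountSpec = field(default_factory=PostCountSpec)
    rate_health_self_pos: float = 0.2
    rate_health_self_neg: float = 0.01
    rate_health_other: float = 0.0
    vocab_size_per_topic: int = 60
    casual_health_rate: float = 0.08
    noise_token_rate: float = 0.10
    english_flag_rate: float = 0.98
    retweet_rate: float = 0.10
    decoration_rates: DecorationRates = field(default_factory=DecorationRates)
    include_declaration_post: bool = False
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "rate_health_self_pos": self.rate_health_self_pos,
            "rate_health_self_neg": self.rate_health_self_neg,
            "rate_health_other": self.rate_health_other,
            "casual_health_rate": self.casual_health_rate,
            "noise_token_rate": self.noise_token_rate,
            "english_flag_rate": self.english_flag_rate,
            "retweet_rate": self.retweet_rate,
            "mention": self.decoration_rates.mention,
            "url": self.decoration_rates.url,
            "numeral": self.decoration_rates.numeral,
            "hashtag": self.decoration_rates.hashtag,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_positive_users < 0 or self.n_control_users < 0:
            raise ValueError("user counts must be non-negative")
        if not 1 <= self.posts_per_user.min <= self.posts_per_user.max:
            raise ValueError("posts_per_user requires 1 <= min <= max")
        if self.posts_per_user.max > 3200:
            raise ValueError("posts_per_user.max is capped at 3200")


@dataclass
class Post:
    post_id: int
    raw_text: str
    true_instance_label: Optional[int]  # 1 self-health, 0 otherwise, None unknown
    topic_tag: str
    is_english: bool = True
    is_retweet: bool = False


@dataclass
class User:
    user_id: str
    label: int
    posts: list[Post]


Corpus = list[User]


def bag_label_oracle(instance_labels: Sequence[int]) -> int:
    """Standard multiple-instance rule: a bag is positive iff any instance is.

    Equivalent to the max over the instance labels.
    """
    labels = list(instance_labels)
    if not labels:
        raise ValueError("bag_label_oracle: empty bag has no defined label")
    for y in labels:
        if y not in (0, 1):
            raise ValueError(f"instance labels must be 0 or 1, got {y!r}")
    return max(labels)


def _topic_vocab(rng: np.random.Generator, seed_words: list[str], size: int,
                 suffix: str) -> list[str]:
    words = list(seed_words[:size])
    while len(words) < size:
        w = "".join(rng.choice(_SYLLABLES, size=3)) + suffix
        if w not in words:
            words.append(w)
    return words


def _n_posts(rng: np.random.Generator, spec: PostCountSpec) -> int:
    if spec.min == spec.max:
        return spec.min
    n = rng.poisson(spec.mean)
    return int(min(max(n, spec.min), spec.max))


def _decorate(rng: np.random.Generator, tokens: list[str],
              rates: DecorationRates, neutral_vocab: list[str]) -> list[str]:
    if rng.random() < rates.mention:
        tokens.insert(0, "@" + "".join(rng.choice(_SYLLABLES, size=2)))
    if rng.random() < rates.numeral:
        tokens.insert(rng.integers(0, len(tokens) + 1), str(rng.integers(1, 5000)))
    if rng.random() < rates.hashtag:
        tokens.append("#" + str(rng.choice(neutral_vocab)))
    if rng.random() < rates.url:
        tokens.append("http://t.co/" + "".join(rng.choice(_SYLLABLES, size=2)))
    return tokens


def _make_post(rng: np.random.Generator, post_id: int, topic: str,
               cfg: GeneratorConfig, health_vocab: list[str],
               neutral_vocab: list[str]) -> Post:
    is_english = bool(rng.random() < cfg.english_flag_rate)
    if not is_english:
        n_tok = int(rng.integers(4, 9))
        text = " ".join(rng.choice(_FOREIGN_TOKENS, size=n_tok))
        return Post(post_id, text, 0 if topic != HEALTH_SELF else 1, topic,
                    is_english=False)
    if topic == HEALTH_SELF:
        template = str(rng.choice(_HEALTH_TEMPLATES))
        own, opposite = _FIRST_PERSON, _THIRD_PERSON
        subject_pool = own
    elif topic == HEALTH_OTHER:
        template = str(rng.choice(_HEALTH_TEMPLATES))
        own, opposite = _THIRD_PERSON, _FIRST_PERSON
        subject_pool = _NAMES if rng.random() < _NAME_RATE else own
    else:
        template = str(rng.choice(_NEUTRAL_TEMPLATES))
        own = opposite = subject_pool = _NEUTRAL_PRONOUNS
    # Casual figurative use of health vocabulary in neutral posts ("so
    # exhausted of this traffic") — an ambiguous-instance confound present
    # in real timelines of both classes.  The instance label stays 0.
    casual = topic == NEUTRAL and rng.random() < cfg.casual_health_rate
    first_n_slot = True
    words = []
    for piece in template.split():
        if piece == "{h}":
            words.append(str(rng.choice(health_vocab)))
        elif piece == "{n}":
            if casual and first_n_slot:
                words.append(str(rng.choice(health_vocab)))
                first_n_slot = False
            else:
                words.append(str(rng.choice(neutral_vocab)))
        elif piece in ("{a}", "{q1}"):
            words.append(str(rng.choice(subject_pool)))
        elif piece in ("{b}", "{q2}"):
            words.append(str(rng.choice(own)))
        elif piece == "{r}":
            pool = opposite if rng.random() < _INCIDENTAL_RATE else own
            words.append(str(rng.choice(pool)))
        else:
            words.append(piece)
    if rng.random() < cfg.noise_token_rate:
        words.append("".join(rng.choice(_SYLLABLES, size=2)))
    words = _decorate(rng, words, cfg.decoration_rates, neutral_vocab)
    is_retweet = bool(rng.random() < cfg.retweet_rate)
    if is_retweet:
        words = ["rt", "@" + "".join(rng.choice(_SYLLABLES, size=2))] + words
    return Post(post_id, " ".join(words), 1 if topic == HEALTH_SELF else 0,
                topic, is_english=True, is_retweet=is_retweet)


def _sample_user(rng: np.random.Generator, user_id: str, positive: bool,
                 cfg: GeneratorConfig, health_vocab: list[str],
                 neutral_vocab: list[str]) -> User:
    rate_self = cfg.rate_health_self_pos if positive else cfg.rate_health_self_neg
    n_posts = _n_posts(rng, cfg.posts_per_user)
    # Rejection-resample the topic sequence so the bag label is consistent
    # with the max rule: positive bags must contain a self-health post,
    # control bags must contain none.
    for _ in range(1000):
        draws = rng.random(n_posts)
        topics = np.where(
            draws < rate_self,
            HEALTH_SELF,
            np.where(draws < rate_self + cfg.rate_health_other, HEALTH_OTHER, NEUTRAL),
        )
        has_self = bool((topics == HEALTH_SELF).any())
        if positive and has_self:
            break
        if not positive and not has_self:
            break
    else:
        # Force consistency rather than loop forever on extreme rates.
        if positive:
            topics[rng.integers(0, n_posts)] = HEALTH_SELF
        else:
            topics = np.where(topics == HEALTH_SELF, NEUTRAL, topics)
    posts = [
        _make_post(rng, j, str(topic), cfg, health_vocab, neutral_vocab)
        for j, topic in enumerate(topics)
    ]
    if positive and cfg.include_declaration_post:
        posts.insert(0, Post(0, _DECLARATION_TEMPLATE, 1, HEALTH_SELF))
        for j, p in enumerate(posts):
            p.post_id = j
    label = bag_label_oracle([p.true_instance_label for p in posts])
    assert label == (1 if positive else 0)
    return User(user_id, label, posts)


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Draw a full corpus; deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    health_vocab = _topic_vocab(rng, _HEALTH_SEED, config.vocab_size_per_topic, "ia")
    neutral_vocab = _topic_vocab(rng, _NEUTRAL_SEED, config.vocab_size_per_topic, "o")
    users: Corpus = []
    for i in range(config.n_positive_users):
        users.append(_sample_user(rng, f"pos{i:04d}", True, config,
                                  health_vocab, neutral_vocab))
    for i in range(config.n_control_users):
        users.append(_sample_user(rng, f"ctl{i:04d}", False, config,
                                  health_vocab, neutral_vocab))
    return users


def write_corpus(corpus: Corpus, path) -> None:
    """One JSON object per user per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for user in corpus:
            record = {
                "user_id": user.user_id,
                "label": user.label,
                "posts": [
                    {
                        "text": p.raw_text,
                        "true_label": p.true_instance_label,
                        "topic": p.topic_tag,
                        "is_english": p.is_english,
                        "is_retweet": p.is_retweet,
                    }
                    for p in user.posts
                ],
            }
            fh.write(json.dumps(record) + "\n")


def read_corpus(path) -> Corpus:
    """Inverse of :func:`write_corpus`; parse errors name the offending line."""
    users: Corpus = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed corpus line {lineno}: {exc}") from exc
            try:
                posts = [
                    Post(
                        post_id=j,
                        raw_text=p["text"],
                        true_instance_label=p.get("true_label"),
                        topic_tag=p.get("topic", "unknown"),
                        is_english=bool(p.get("is_english", True)),
                        is_retweet=bool(p.get("is_retweet", False)),
                    )
                    for j, p in enumerate(record["posts"])
                ]
                users.append(User(record["user_id"], int(record["label"]), posts))
            except (KeyError, TypeError) as exc:
                raise ValueError(f"malformed corpus line {lineno}: {exc}") from exc
    return users


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "posts_per_user" in d and isinstance(d["posts_per_user"], dict):
        d["posts_per_user"] = PostCountSpec(**d["posts_per_user"])
    if "decoration_rates" in d and isinstance(d["decoration_rates"], dict):
        d["decoration_rates"] = DecorationRates(**d["decoration_rates"])
    return GeneratorConfig(**d)
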