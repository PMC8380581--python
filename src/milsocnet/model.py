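"""MIL-SocNet and MILA-SocNet: hierarchical attention networks trained on
bag labels only.

A user is a bag of posts.  Each post's tokens are embedded, encoded by a
bidirectional GRU and pooled by word attention into a tweet vector t_j,
which a softmax head turns into an instance probability pair p_j — with no
instance-level supervision, p_j is shaped purely by the user-level loss.
The ordered sequence of p_j (the *user representation*; in the MILA
variant each element is the concatenation of the post's pronoun-category
fractions s_j with p_j) runs through a second bidirectional GRU, tweet
attention pools the hidden states into a user vector v, and a final
softmax predicts the bag label.  Training minimizes user-level
cross-entropy with dropout and early stopping; Adam and AdaMod optimizers
are provided.

All attention is computed over valid (unmasked) positions only by default;
zero-padded posts and tokens then provably cannot influence any output
(the ``mask_attention=False`` switch restores naive attention over the
padded grid for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ModelOutput",
    "BagDataset",
    "init_params",
    "count_params",
    "tweet_encode",
    "word_attention",
    "classify_tweet",
    "build_user_representation",
    "user_encode",
    "tweet_attention",
    "classify_user",
    "forward",
    "predict",
    "train",
    "oriented_instance_scores",
    "save_checkpoint",
    "load_checkpoint",
]

MIL = "mil"
MILA = "mila"


@dataclass
class ModelConfig:
    variant: str = MILA
    embedding_dim: int = 100
    word_gru_hidden: int = 32
    user_gru_hidden: int = 32
    attention_dim: int = 32
    dropout_rate: float = 0.3
    max_posts: int = 2000
    max_tokens: int = 55
    pronoun_dim: int = 7
    use_full_prob_vector: bool = True
    freeze_embeddings: bool = False
    mask_attention: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.variant not in (MIL, MILA):
            raise ValueError(f"variant must be '{MIL}' or '{MILA}'")
        for name in ("embedding_dim", "word_gru_hidden", "user_gru_hidden",
                     "attention_dim", "max_posts", "max_tokens"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.variant == MILA and self.pronoun_dim <= 0:
            raise ValueError("MILA variant requires a positive pronoun_dim")

    @property
    def rep_dim(self) -> int:
        """Width of one user-representation element."""
        d = 2 if self.use_full_prob_vector else 1
        if self.variant == MILA:
            d += self.pronoun_dim
        return d


@dataclass
class TrainConfig:
    optimizer: str = "adam"  # or "adamod"
    learning_rate: float = 5e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 3
    clip_norm: float = 5.0
    seed: int = 0


@dataclass
class ModelOutput:
    """Eval-mode outputs for a batch of bags (plain arrays)."""

    user_probs: np.ndarray  # (U, 2)
    instance_probs: np.ndarray  # (U, P, 2); zero rows at padded posts
    word_attention: np.ndarray  # (U, P, T)
    tweet_attention: np.ndarray  # (U, P)
    tweet_vectors: np.ndarray  # (U, P, 2*word_gru_hidden)
    user_vectors: np.ndarray  # (U, 2*user_gru_hidden)


@dataclass
class BagDataset:
    """Stacked fixed-shape bags ready for the network."""

    token_ids: np.ndarray  # (U, P, T)
    token_mask: np.ndarray
    post_mask: np.ndarray  # (U, P)
    labels: np.ndarray  # (U,)
    pronouns: Optional[np.ndarray] = None  # (U, P, pronoun_dim)

    def __len__(self) -> int:
        return self.token_ids.shape[0]

    def subset(self, idx) -> "BagDataset":
        return BagDataset(
            self.token_ids[idx],
            self.token_mask[idx],
            self.post_mask[idx],
            self.labels[idx],
            None if self.pronouns is None else self.pronouns[idx],
        )


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _gru_block(rng, n_in, hid, prefix) -> dict[str, np.ndarray]:
    return {
        f"{prefix}/W": _glorot(rng, n_in, 3 * hid),
        f"{prefix}/U": _glorot(rng, hid, 3 * hid),
        f"{prefix}/b": np.zeros(3 * hid),
    }


def init_params(
    config: ModelConfig,
    vocab_size: int,
    embedding: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Seeded Glorot-uniform initialization of every trainable array."""
    rng = np.random.default_rng(config.seed)
    if embedding is None:
        w_e = rng.uniform(-0.05, 0.05, size=(vocab_size, config.embedding_dim))
        w_e[0] = 0.0
    else:
        if embedding.shape != (vocab_size, config.embedding_dim):
            raise ValueError("embedding shape does not match vocab/config")
        w_e = embedding.astype(np.float64).copy()
    hw, hu, a = config.word_gru_hidden, config.user_gru_hidden, config.attention_dim
    params = {"W_e": w_e}
    params.update(_gru_block(rng, config.embedding_dim, hw, "wgru_f"))
    params.update(_gru_block(rng, config.embedding_dim, hw, "wgru_b"))
    params.update({
        "W_w": _glorot(rng, 2 * hw, a),
        "b_w": np.zeros(a),
        "u_w": _glorot(rng, a, 1),
        "W_c": _glorot(rng, 2 * hw, 2),
        "b_c": np.zeros(2),
    })
    params.update(_gru_block(rng, config.rep_dim, hu, "ugru_f"))
    params.update(_gru_block(rng, config.rep_dim, hu, "ugru_b"))
    params.update({
        "W_t": _glorot(rng, 2 * hu, a),
        "b_t": np.zeros(a),
        "u_t": _glorot(rng, a, 1),
        "W_u": _glorot(rng, 2 * hu, 2),
        "b_u": np.zeros(2),
    })
    return params


def count_params(params: dict[str, np.ndarray], config: ModelConfig) -> int:
    """Number of trainable scalars (the K fed to model-comparison scores)."""
    total = 0
    for name, arr in params.items():
        if name == "W_e" and config.freeze_embeddings:
            continue
        total += arr.size
    return total


# ---------------------------------------------------------------------------
# Network blocks.  Each mirrors one stage of the architecture and operates
# on autodiff Tensors so the composed forward pass is differentiable.
# ---------------------------------------------------------------------------

def _bigru(x: Tensor, mask: np.ndarray, p: dict[str, Tensor], prefix: str) -> Tensor:
    fwd = ad.gru_layer(x, mask, p[f"{prefix}_f/W"], p[f"{prefix}_f/U"],
                       p[f"{prefix}_f/b"])
    bwd = ad.gru_layer(x, mask, p[f"{prefix}_b/W"], p[f"{prefix}_b/U"],
                       p[f"{prefix}_b/b"], reverse=True)
    return ad.concat([fwd, bwd], axis=-1)


def tweet_encode(x: Tensor, token_mask: np.ndarray, p: dict[str, Tensor]) -> Tensor:
    """Word-level BiGRU: embedded tokens (N,T,E) -> hidden states (N,T,2*hw)."""
    return _bigru(x, token_mask, p, "wgru")


def word_attention(
    h: Tensor, token_mask: np.ndarray, p: dict[str, Tensor]
) -> tuple[Tensor, Tensor]:
    """tanh attention over valid tokens: returns (tweet vectors, weights)."""
    u = ad.tanh(ad.dense(h, p["W_w"], p["b_w"]))
    scores = ad.reshape(ad.matmul(u, p["u_w"]), h.data.shape[:-1])
    a = ad.masked_softmax(scores, token_mask)
    return ad.attend(a, h), a


def classify_tweet(t: Tensor, p: dict[str, Tensor]) -> Tensor:
    """Instance head: softmax(W_c t + b_c) on the 2-simplex per post."""
    return ad.softmax(ad.dense(t, p["W_c"], p["b_c"]))


def build_user_representation(
    probs: Tensor,
    post_mask: np.ndarray,
    config: ModelConfig,
    pronouns: Optional[np.ndarray] = None,
) -> Tensor:
    """Per-post inputs to the user encoder; zero rows at padded slots.

    MIL: element j is p_j.  MILA: element j is concat(s_j, p_j).
    """
    if not config.use_full_prob_vector:
        probs = ad.matmul(probs, ad.constant(np.array([[0.0], [1.0]])))
    if config.variant == MILA:
        if pronouns is None:
            raise ValueError("MILA variant requires pronoun features")
        rep = ad.concat([ad.constant(pronouns), probs], axis=-1)
    else:
        rep = probs
    return ad.mul(rep, np.asarray(post_mask, dtype=np.float64)[:, :, None])


def user_encode(rep: Tensor, post_mask: np.ndarray, p: dict[str, Tensor]) -> Tensor:
    """Post-level BiGRU over the user representation -> (U,P,2*hu)."""
    return _bigru(rep, post_mask, p, "ugru")


def tweet_attention(
    h: Tensor, post_mask: np.ndarray, p: dict[str, Tensor]
) -> tuple[Tensor, Tensor]:
    """tanh attention over valid posts: returns (user vectors, weights)."""
    u = ad.tanh(ad.dense(h, p["W_t"], p["b_t"]))
    scores = ad.reshape(ad.matmul(u, p["u_t"]), h.data.shape[:-1])
    alpha = ad.masked_softmax(scores, post_mask)
    return ad.attend(alpha, h), alpha


def classify_user(v: Tensor, p: dict[str, Tensor]) -> Tensor:
    return ad.softmax(ad.dense(v, p["W_u"], p["b_u"]))


def _user_logits(v: Tensor, p: dict[str, Tensor]) -> Tensor:
    return ad.dense(v, p["W_u"], p["b_u"])


def _dropout(x: Tensor, rate: float, rng: Optional[np.random.Generator]) -> Tensor:
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return ad.mul(x, keep)


def _graph(
    wrapped: dict[str, Tensor],
    data: BagDataset,
    config: ModelConfig,
    train_rng: Optional[np.random.Generator] = None,
) -> dict[str, Tensor]:
    """Build the full computation graph for a batch of bags."""
    n_users, n_posts, n_tok = data.token_ids.shape
    flat_ids = data.token_ids.reshape(-1, n_tok)
    flat_tmask = data.token_mask.reshape(-1, n_tok)
    att_tmask = flat_tmask if config.mask_attention else np.ones_like(flat_tmask)
    att_pmask = (data.post_mask if config.mask_attention
                 else np.ones_like(data.post_mask))

    x = ad.lookup(wrapped["W_e"], flat_ids)
    h_words = tweet_encode(x, flat_tmask, wrapped)
    h_words = _dropout(h_words, config.dropout_rate, train_rng)
    t_vec, a_words = word_attention(h_words, att_tmask, wrapped)
    p_inst = classify_tweet(t_vec, wrapped)

    p_bags = ad.reshape(p_inst, (n_users, n_posts, 2))
    # Zero padded posts here too: their tweet vector is zero, so the head
    # would otherwise emit softmax(b_c) for them.
    p_bags = ad.mul(p_bags, data.post_mask[:, :, None].astype(np.float64))
    rep = build_user_representation(p_bags, data.post_mask, config, data.pronouns)
    h_posts = user_encode(rep, data.post_mask, wrapped)
    h_posts = _dropout(h_posts, config.dropout_rate, train_rng)
    v, alpha = tweet_attention(h_posts, att_pmask, wrapped)
    logits = _user_logits(v, wrapped)
    return {
        "instance_probs": p_bags,
        "word_attention": a_words,
        "tweet_attention": alpha,
        "tweet_vectors": t_vec,
        "user_vectors": v,
        "user_logits": logits,
        "user_probs": ad.softmax(logits),
    }


def _wrap(params: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: ad.parameter(v) for k, v in params.items()}


def forward(
    params: dict[str, np.ndarray], data: BagDataset, config: ModelConfig
) -> ModelOutput:
    """Deterministic eval-mode forward pass (dropout off)."""
    nodes = _graph(_wrap(params), data, config, train_rng=None)
    n_users, n_posts, n_tok = data.token_ids.shape
    return ModelOutput(
        user_probs=nodes["user_probs"].data,
        instance_probs=nodes["instance_probs"].data,
        word_attention=nodes["word_attention"].data.reshape(n_users, n_posts, n_tok),
        tweet_attention=nodes["tweet_attention"].data,
        tweet_vectors=nodes["tweet_vectors"].data.reshape(n_users, n_posts, -1),
        user_vectors=nodes["user_vectors"].data,
    )


def predict(
    params: dict[str, np.ndarray],
    data: BagDataset,
    config: ModelConfig,
    batch_size: int = 64,
) -> ModelOutput:
    """Eval forward in batches; concatenates the per-batch outputs."""
    outs = [
        forward(params, data.subset(slice(i, i + batch_size)), config)
        for i in range(0, len(data), batch_size)
    ]
    return ModelOutput(*[
        np.concatenate([getattr(o, f) for o in outs], axis=0)
        for f in ("user_probs", "instance_probs", "word_attention",
                  "tweet_attention", "tweet_vectors", "user_vectors")
    ])


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdaMod(Adam):
    """Adam with memory-smoothed, element-wise upper bounds on step sizes.

    Keeps an exponential moving average s of the adaptive learning rates
    eta = lr / (sqrt(v_hat) + eps) and clips each update's rate at that
    average: theta -= min(eta, s) * m_hat.
    """

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, beta3=0.9999, eps=1e-8):
        super().__init__(lr, beta1, beta2, eps)
        self.b3 = beta3
        self.s: dict[str, np.ndarray] = {}

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            eta = self.lr / (np.sqrt(vhat) + self.eps)
            s = self.s.setdefault(k, np.zeros_like(g))
            s += (1 - self.b3) * (eta - s)
            params[k] -= np.minimum(eta, s) * mhat


def _make_optimizer(cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return Adam(lr=cfg.learning_rate)
    if cfg.optimizer == "adamod":
        return AdaMod(lr=cfg.learning_rate)
    raise ValueError(f"unknown optimizer {cfg.optimizer!r}")


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _batch_loss_and_grads(params_np, batch, config, rng):
    wrapped = _wrap(params_np)
    nodes = _graph(wrapped, batch, config, train_rng=rng)
    loss = ad.nll_from_logits(nodes["user_logits"], batch.labels)
    loss.backward()
    grads = {
        k: (t.grad if t.grad is not None else np.zeros_like(t.data))
        for k, t in wrapped.items()
    }
    if config.freeze_embeddings:
        grads.pop("W_e", None)
    else:
        grads["W_e"][0] = 0.0  # padding row stays zero
    return float(loss.data), grads


def _dataset_loss(params, data, config, batch_size=64) -> float:
    total, n = 0.0, 0
    for i in range(0, len(data), batch_size):
        sub = data.subset(slice(i, i + batch_size))
        nodes = _graph(_wrap(params), sub, config, train_rng=None)
        loss = ad.nll_from_logits(nodes["user_logits"], sub.labels)
        total += float(loss.data) * len(sub)
        n += len(sub)
    return total / max(n, 1)


def train(
    params: dict[str, np.ndarray],
    train_set: BagDataset,
    val_set: BagDataset,
    config: ModelConfig,
    train_config: Optional[TrainConfig] = None,
) -> tuple[dict[str, np.ndarray], dict[str, list[float]]]:
    """Minimize user-level cross-entropy with early stopping.

    Returns the parameters with the best validation loss and the epoch-wise
    history {"train_loss": [...], "val_loss": [...]}.  Deterministic given
    the seeds (single-threaded NumPy graph).
    """
    tc = train_config or TrainConfig()
    rng = np.random.default_rng(tc.seed)
    params = {k: v.copy() for k, v in params.items()}
    opt = _make_optimizer(tc)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    stale = 0
    n = len(train_set)
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, tc.batch_size):
            batch = train_set.subset(order[start : start + tc.batch_size])
            loss, grads = _batch_loss_and_grads(params, batch, config, rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches} (lr={tc.learning_rate})"
                )
            _clip_global_norm(grads, tc.clip_norm)
            opt.step(params, grads)
            if not config.freeze_embeddings:
                params["W_e"][0] = 0.0
            epoch_loss += loss
            n_batches += 1
        val_loss = _dataset_loss(params, val_set, config)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break
    return best_params, history


def oriented_instance_scores(
    instance_probs: np.ndarray,
    post_mask: np.ndarray,
    predicted_labels: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Per-post positive-instance scores with the class index oriented from
    bag-level predictions.

    With bag-only supervision the instance head's class order is not
    identified (swapping its two outputs can be absorbed downstream).  The
    mental-health instance class is taken to be the one whose mean per-post
    probability is higher among users the model predicts positive than
    among users it predicts negative — computed purely from model outputs.
    Returns (scores of shape (U, P), chosen class index).
    """
    mask = post_mask.astype(bool)
    pos_users = predicted_labels == 1
    if pos_users.any() and (~pos_users).any():
        mean_pos = instance_probs[pos_users][mask[pos_users]][:, 1].mean()
        mean_neg = instance_probs[~pos_users][mask[~pos_users]][:, 1].mean()
        cls = 1 if mean_pos >= mean_neg else 0
    else:
        cls = 1
    return instance_probs[:, :, cls], cls


def save_checkpoint(path, params: dict[str, np.ndarray], config: ModelConfig) -> None:
    """Single-file archive of named parameter arrays plus the config."""
    import json

    np.savez(path, __config__=json.dumps(asdict(config)),
             **{f"param/{k}": v for k, v in params.items()})


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], ModelConfig]:
    import json

    with np.load(path, allow_pickle=False) as archive:
        config = ModelConfig(**json.loads(str(archive["__config__"])))
        params = {
            k[len("param/"):]: archive[k]
            for k in archive.files
            if k.startswith("param/")
        }
    return params, config
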