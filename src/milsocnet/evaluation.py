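"""Evaluation protocol: chunked holdout cross-validation, classification
metrics, ROC/AUC, log-likelihood, small-sample corrected AIC, a majority
baseline, and attention-based explanations.

The cross-validation scheme mirrors cohort studies with many more controls
than cases: the positive users are split into equal chunks, each round
pairs one chunk with *all* control users, and a stratified 20% of that
round's users is held out as the test set.  Metrics are arithmetic means
across rounds.  Model comparison uses the corrected Akaike information
criterion AICc = -2 lnL + 2K + 2K(K+1)/(n-K-1), where K counts trainable
parameters, lnL is the log-likelihood of the observed test labels under
the model's probabilities, and n is the per-round test-set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn import metrics as skm
from sklearn.model_selection import train_test_split

from . import model as mdl
from .preprocessing import encode_corpus, filter_users, build_vocabulary
from .pronouns import features_for_bag
from .synthetic import Corpus

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "ModelComparisonRecord",
    "make_folds",
    "compute_metrics",
    "roc_auc",
    "log_likelihood",
    "aicc",
    "majority_baseline",
    "explain",
    "run_experiment",
    "holdout_run",
]

PROB_FLOOR = 1e-12


@dataclass
class FoldPlan:
    round_index: int  # 1-based
    positive_chunk: list[str]
    controls: list[str]
    train_ids: list[str]
    test_ids: list[str]
    seed: int


@dataclass
class MetricsReport:
    accuracy: float
    precision: float  # class-weighted
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class ModelComparisonRecord:
    model_name: str
    k: int
    ln_likelihood: float
    n: int
    aicc: float


def make_folds(
    corpus: Corpus,
    n_chunks: int = 4,
    test_frac: float = 0.2,
    seed: int = 0,
) -> list[FoldPlan]:
    """Split positives into near-equal chunks; each round = one chunk plus
    all controls, with a stratified `test_frac` holdout inside the round.

    Chunk sizes differ by at most one (round-robin after a seeded shuffle).
    """
    pos_ids = [u.user_id for u in corpus if u.label == 1]
    neg_ids = [u.user_id for u in corpus if u.label == 0]
    if not pos_ids or not neg_ids:
        raise ValueError("both classes must be present to build folds")
    rng = np.random.default_rng(seed)
    pos_ids = [pos_ids[i] for i in rng.permutation(len(pos_ids))]
    chunks: list[list[str]] = [pos_ids[i::n_chunks] for i in range(n_chunks)]
    plans = []
    for r, chunk in enumerate(chunks, start=1):
        ids = chunk + neg_ids
        strata = [1] * len(chunk) + [0] * len(neg_ids)
        train_ids, test_ids = train_test_split(
            ids, test_size=test_frac, stratify=strata,
            random_state=(seed + r) % (2**32),
        )
        plans.append(FoldPlan(r, list(chunk), list(neg_ids),
                              list(train_ids), list(test_ids), seed))
    return plans


def compute_metrics(true_labels, predicted_labels) -> MetricsReport:
    """Confusion-matrix metrics; headline P/R/F1 are class-weighted."""
    y, yhat = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.size == 0:
        raise ValueError("cannot compute metrics on empty input")
    if y.shape != yhat.shape:
        raise ValueError("label vectors must have equal length")
    tn, fp, fn, tp = skm.confusion_matrix(y, yhat, labels=[0, 1]).ravel()
    prec, rec, f1, _ = skm.precision_recall_fscore_support(
        y, yhat, average="weighted", zero_division=0
    )
    per_class = {}
    p_c, r_c, f_c, s_c = skm.precision_recall_fscore_support(
        y, yhat, labels=[0, 1], zero_division=0
    )
    for i, cls in enumerate(("0", "1")):
        per_class[cls] = {
            "precision": float(p_c[i]),
            "recall": float(r_c[i]),
            "f1": float(f_c[i]),
            "support": int(s_c[i]),
        }
    return MetricsReport(
        accuracy=float(skm.accuracy_score(y, yhat)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        per_class=per_class,
    )


def roc_auc(true_labels, scores) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr) and trapezoidal AUC."""
    y = np.asarray(true_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes in the truth vector")
    fpr, tpr, _ = skm.roc_curve(y, np.asarray(scores))
    return np.column_stack([fpr, tpr]), float(skm.auc(fpr, tpr))


def log_likelihood(true_labels, prob_pairs) -> float:
    """Sum over users of ln p(observed label); probabilities floored at 1e-12."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(prob_pairs, dtype=float)
    if p.shape[0] != y.shape[0]:
        raise ValueError("labels and probability pairs differ in length")
    chosen = np.clip(p[np.arange(len(y)), y], PROB_FLOOR, 1.0)
    return float(np.log(chosen).sum())


def aicc(ln_likelihood: float, k: int, n: int) -> float:
    """Corrected AIC: -2 lnL + 2K + 2K(K+1)/(n-K-1).

    The correction term penalizes complexity relative to sample size; it is
    undefined at n = K + 1.
    """
    if n == k + 1:
        raise ValueError("AICc undefined at n = K + 1 (zero denominator)")
    return -2.0 * ln_likelihood + 2.0 * k + (2.0 * k * (k + 1)) / (n - k - 1)


def majority_baseline(labels) -> float:
    """Accuracy of always predicting the most frequent class."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("majority baseline needs at least one label")
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / y.size)


@dataclass
class ExplainedPost:
    rank: int
    post_index: int
    weight: float
    text: str


def explain(
    output: mdl.ModelOutput,
    user_index: int,
    post_texts: Sequence[str],
    top_k: int = 1,
) -> dict[str, list[ExplainedPost]]:
    """Rank a user's posts by tweet-attention weight.

    Returns {"top": [...], "bottom": [...]}, each holding up to top_k posts
    (truncated when the bag has fewer valid posts), top sorted by
    non-increasing weight, bottom by non-decreasing weight.
    """
    alpha = output.tweet_attention[user_index]
    valid = np.flatnonzero(alpha > 0) if (alpha > 0).any() else np.arange(len(alpha))
    valid = valid[valid < len(post_texts)]
    order = valid[np.argsort(-alpha[valid], kind="stable")]
    k = min(top_k, len(order))
    top = [
        ExplainedPost(i + 1, int(j), float(alpha[j]), post_texts[j])
        for i, j in enumerate(order[:k])
    ]
    bottom = [
        ExplainedPost(i + 1, int(j), float(alpha[j]), post_texts[j])
        for i, j in enumerate(order[::-1][:k])
    ]
    return {"top": top, "bottom": bottom}


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------


def _prepare_dataset(corpus, vocab, config: mdl.ModelConfig) -> mdl.BagDataset:
    ids, tmask, pmask, labels, bags = encode_corpus(
        corpus, vocab, config.max_posts, config.max_tokens
    )
    pron = None
    if config.variant == mdl.MILA:
        pron = np.stack([
            features_for_bag(b.tokens, max_posts=config.max_posts) for b in bags
        ])
    return mdl.BagDataset(ids, tmask, pmask, labels, pron)


def holdout_run(
    corpus: Corpus,
    config: mdl.ModelConfig,
    train_config: Optional[mdl.TrainConfig] = None,
    test_frac: float = 0.2,
    val_frac: float = 0.1,
    seed: int = 0,
    min_posts: int = 10,
):
    """Train one model on a stratified holdout split of a corpus.

    Splits users into train/validation/test (stratified by bag label),
    fits the configured variant, and returns a dict with the metrics
    report, test ROC/AUC, instance-level outputs and the fitted params.
    """
    tc = train_config or mdl.TrainConfig(seed=seed)
    corpus = filter_users(corpus, min_posts=min_posts)
    labels = [u.label for u in corpus]
    idx = np.arange(len(corpus))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, stratify=labels, random_state=seed % (2**32)
    )
    tr_labels = [labels[i] for i in train_idx]
    train_idx, val_idx = train_test_split(
        train_idx, test_size=val_frac, stratify=tr_labels,
        random_state=(seed + 1) % (2**32),
    )
    vocab = build_vocabulary([corpus[i] for i in train_idx])
    dataset = _prepare_dataset(corpus, vocab, config)
    params = mdl.init_params(config, len(vocab))
    fitted, history = mdl.train(
        params, dataset.subset(train_idx), dataset.subset(val_idx), config, tc
    )
    test_set = dataset.subset(test_idx)
    out = mdl.predict(fitted, test_set, config)
    yhat = out.user_probs.argmax(axis=1)
    report = compute_metrics(test_set.labels, yhat)
    _, auc = roc_auc(test_set.labels, out.user_probs[:, 1])
    inst_scores, inst_class = mdl.oriented_instance_scores(
        out.instance_probs, test_set.post_mask, yhat
    )
    return {
        "metrics": report,
        "auc": auc,
        "history": history,
        "params": fitted,
        "vocab": vocab,
        "config": config,
        "test_corpus": [corpus[i] for i in test_idx],
        "test_set": test_set,
        "test_output": out,
        "instance_scores": inst_scores,
        "instance_class": inst_class,
    }


def instance_auc(result: dict) -> float:
    """Instance-level AUC of oriented per-post scores against the hidden
    true instance labels of a synthetic test set (valid posts only)."""
    test_corpus = result["test_corpus"]
    test_set = result["test_set"]
    scores, truths = [], []
    for i, user in enumerate(test_corpus):
        n = int(test_set.post_mask[i].sum())
        posts = user.posts[-n:]
        for j, post in enumerate(posts):
            if post.true_instance_label is None:
                continue
            scores.append(result["instance_scores"][i, j])
            truths.append(post.true_instance_label)
    _, auc = roc_auc(truths, scores)
    return auc


def run_experiment(
    corpus: Corpus,
    config: mdl.ModelConfig,
    train_config: Optional[mdl.TrainConfig] = None,
    n_chunks: int = 4,
    test_frac: float = 0.2,
    val_frac: float = 0.1,
    seed: int = 0,
    min_posts: int = 10,
    model_name: Optional[str] = None,
) -> dict:
    """Full protocol: chunked folds -> train per round -> averaged metrics,
    pooled ROC and a model-comparison record (K, lnL, n, AICc).

    lnL, n and AICc are averaged across rounds, matching how the protocol
    reports them.  Returns a JSON-serializable dict plus per-round reports.
    """
    corpus = filter_users(corpus, min_posts=min_posts)
    by_id = {u.user_id: u for u in corpus}
    folds = make_folds(corpus, n_chunks=n_chunks, test_frac=test_frac, seed=seed)
    tc = train_config or mdl.TrainConfig(seed=seed)
    rounds = []
    pooled_scores: list[float] = []
    pooled_truth: list[int] = []
    lnls, aiccs, ns = [], [], []
    k_params = 0
    for plan in folds:
        train_users = [by_id[i] for i in plan.train_ids]
        test_users = [by_id[i] for i in plan.test_ids]
        tr_labels = [u.label for u in train_users]
        tr_idx, val_idx = train_test_split(
            np.arange(len(train_users)), test_size=val_frac, stratify=tr_labels,
            random_state=(seed + 100 + plan.round_index) % (2**32),
        )
        vocab = build_vocabulary([train_users[i] for i in tr_idx])
        train_ds = _prepare_dataset(train_users, vocab, config)
        test_ds = _prepare_dataset(test_users, vocab, config)
        params = mdl.init_params(config, len(vocab))
        fitted, _ = mdl.train(
            params, train_ds.subset(tr_idx), train_ds.subset(val_idx), config, tc
        )
        k_params = mdl.count_params(fitted, config)
        out = mdl.predict(fitted, test_ds, config)
        yhat = out.user_probs.argmax(axis=1)
        rounds.append(compute_metrics(test_ds.labels, yhat))
        pooled_scores.extend(out.user_probs[:, 1].tolist())
        pooled_truth.extend(test_ds.labels.tolist())
        lnl = log_likelihood(test_ds.labels, out.user_probs)
        lnls.append(lnl)
        ns.append(len(test_users))
        aiccs.append(aicc(lnl, k_params, len(test_users)))
    curve, pooled_auc = roc_auc(pooled_truth, pooled_scores)
    mean = lambda xs: float(np.mean(xs))
    record = ModelComparisonRecord(
        model_name=model_name or config.variant,
        k=k_params,
        ln_likelihood=mean(lnls),
        n=int(np.mean(ns)),
        aicc=mean(aiccs),
    )
    return {
        "per_round": rounds,
        "mean_metrics": {
            "accuracy": mean([r.accuracy for r in rounds]),
            "precision": mean([r.precision for r in rounds]),
            "recall": mean([r.recall for r in rounds]),
            "f1": mean([r.f1 for r in rounds]),
        },
        "roc_curve": curve,
        "auc": pooled_auc,
        "comparison": record,
        "folds": folds,
    }
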