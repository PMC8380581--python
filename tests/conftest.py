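import numpy as np
import pytest

from milsocnet import synthetic as syn
from milsocnet import model as mdl
from milsocnet.evaluation import holdout_run, instance_auc


def small_model_config(variant: str, seed: int, **overrides) -> mdl.ModelConfig:
    """Compact dimensions used for CPU-sized experiments throughout the suite."""
    kwargs = dict(
        variant=variant,
        embedding_dim=32,
        word_gru_hidden=16,
        user_gru_hidden=16,
        attention_dim=16,
        max_posts=50,
        max_tokens=16,
        seed=seed,
    )
    kwargs.update(overrides)
    return mdl.ModelConfig(**kwargs)


def small_train_config(seed: int, **overrides) -> mdl.TrainConfig:
    kwargs = dict(seed=seed, max_epochs=10, patience=2)
    kwargs.update(overrides)
    return mdl.TrainConfig(**kwargs)


@pytest.fixture(scope="session")
def default_corpus_runs():
    """Three seeded MILA fits on the default synthetic corpus.

    Shared by the bag-label accuracy, instance-recovery and attention
    -explanation tests so the expensive training happens once.
    """
    runs = []
    for seed in (1, 2, 3):
        corpus = syn.generate_corpus(syn.GeneratorConfig(seed=seed))
        result = holdout_run(
            corpus,
            small_model_config("mila", seed),
            small_train_config(seed),
            seed=seed,
        )
        result["instance_auc"] = instance_auc(result)
        runs.append(result)
    return runs


@pytest.fixture
def tiny_corpus():
    """A small, fast corpus for plumbing tests."""
    cfg = syn.GeneratorConfig(
        n_positive_users=10,
        n_control_users=10,
        posts_per_user=syn.PostCountSpec(8, 8, 8.0),
        seed=42,
    )
    return syn.generate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
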