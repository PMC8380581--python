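"""The attention networks: block-level oracles, invariants, training."""

import numpy as np
import pytest

from milsocnet import autodiff as ad
from milsocnet import model as mdl
from milsocnet import synthetic as syn
from milsocnet.evaluation import holdout_run
from milsocnet.preprocessing import build_vocabulary, encode_corpus
from milsocnet.pronouns import features_for_bag


def make_random_dataset(rng, n_users=4, n_posts=6, n_tokens=8, vocab_size=30,
                        with_pronouns=True):
    """Random bags with variable post/token counts and proper masks."""
    ids = np.zeros((n_users, n_posts, n_tokens), dtype=np.int64)
    tmask = np.zeros_like(ids)
    pmask = np.zeros((n_users, n_posts), dtype=np.int64)
    for u in range(n_users):
        k_posts = int(rng.integers(1, n_posts + 1))
        pmask[u, :k_posts] = 1
        for j in range(k_posts):
            k_tok = int(rng.integers(1, n_tokens + 1))
            tmask[u, j, :k_tok] = 1
            ids[u, j, :k_tok] = rng.integers(2, vocab_size, size=k_tok)
    labels = rng.integers(0, 2, size=n_users)
    pron = None
    if with_pronouns:
        pron = rng.random((n_users, n_posts, 7)) * pmask[:, :, None]
    return mdl.BagDataset(ids, tmask, pmask, labels, pron)


@pytest.fixture
def dataset(rng):
    return make_random_dataset(rng)


@pytest.fixture
def config():
    return mdl.ModelConfig(variant="mila", embedding_dim=10, word_gru_hidden=4,
                           user_gru_hidden=5, attention_dim=3, max_posts=6,
                           max_tokens=8, seed=0)


@pytest.fixture
def params(config):
    return mdl.init_params(config, vocab_size=30)


class TestConfig:
    def test_rep_dim_by_variant(self):
        assert mdl.ModelConfig(variant="mil").rep_dim == 2
        assert mdl.ModelConfig(variant="mila", pronoun_dim=7).rep_dim == 9
        assert mdl.ModelConfig(variant="mil", use_full_prob_vector=False).rep_dim == 1

    def test_invalid_variant_and_dims_rejected(self):
        with pytest.raises(ValueError):
            mdl.ModelConfig(variant="cnn")
        with pytest.raises(ValueError):
            mdl.ModelConfig(word_gru_hidden=0)
        with pytest.raises(ValueError):
            mdl.ModelConfig(variant="mila", pronoun_dim=0)


class TestGRUAgainstHandUnrolledRecurrence:
    def test_two_step_scalar_gru(self):
        """Unroll the gated recurrence by hand for hidden size 1."""
        wz, wr, wn = 0.5, -0.3, 0.8
        uz, ur, un = 0.2, 0.4, -0.6
        bz, br, bn = 0.1, -0.1, 0.05
        x1, x2 = 1.0, -2.0

        def sig(a):
            return 1.0 / (1.0 + np.exp(-a))

        h = 0.0
        expected = []
        for xv in (x1, x2):
            z = sig(wz * xv + uz * h + bz)
            r = sig(wr * xv + ur * h + br)
            n = np.tanh(wn * xv + bn + r * (un * h))
            h = (1 - z) * n + z * h
            expected.append(h)

        w = np.array([[wz, wr, wn]])
        u = np.array([[uz, ur, un]])
        b = np.array([bz, br, bn])
        x = np.array([[[x1], [x2]]])
        out = ad.gru_layer(ad.Tensor(x), np.ones((1, 2)), ad.Tensor(w),
                           ad.Tensor(u), ad.Tensor(b))
        np.testing.assert_allclose(out.data[0, :, 0], expected, atol=1e-12)

    def test_reversal_symmetry(self, rng):
        """The backward direction equals the forward direction on the
        time-reversed input."""
        x = rng.normal(size=(2, 5, 3))
        mask = np.ones((2, 5))
        w = ad.Tensor(rng.normal(size=(3, 12)))
        u = ad.Tensor(rng.normal(size=(4, 12)))
        b = ad.Tensor(rng.normal(size=12))
        rev = ad.gru_layer(ad.Tensor(x), mask, w, u, b, reverse=True)
        fwd_flip = ad.gru_layer(ad.Tensor(x[:, ::-1]), mask, w, u, b)
        np.testing.assert_allclose(rev.data, fwd_flip.data[:, ::-1], atol=1e-12)


class TestWordAttention:
    def test_single_valid_token_gets_weight_one(self, rng, params):
        p = {k: ad.Tensor(v) for k, v in params.items()}
        h = ad.Tensor(rng.normal(size=(1, 4, 8)))
        mask = np.array([[1, 0, 0, 0]])
        t, a = mdl.word_attention(h, mask, p)
        np.testing.assert_allclose(a.data, [[1, 0, 0, 0]])
        np.testing.assert_allclose(t.data[0], h.data[0, 0])

    def test_identical_states_get_uniform_weights(self, rng, params):
        p = {k: ad.Tensor(v) for k, v in params.items()}
        h = np.tile(rng.normal(size=(1, 1, 8)), (1, 4, 1))
        _, a = mdl.word_attention(ad.Tensor(h), np.ones((1, 4)), p)
        np.testing.assert_allclose(a.data, 0.25, atol=1e-12)

    @pytest.mark.parametrize("level", ["word", "tweet"])
    def test_matches_direct_formula_on_random_instances(self, rng, params, level):
        """tanh-projection attention against an independent closed-form
        computation, 100 random cases, 1e-6."""
        p = {k: ad.Tensor(v) for k, v in params.items()}
        if level == "word":
            w, b, ctx, width, fn = (params["W_w"], params["b_w"], params["u_w"],
                                    8, mdl.word_attention)
        else:
            w, b, ctx, width, fn = (params["W_t"], params["b_t"], params["u_t"],
                                    10, mdl.tweet_attention)
        for _ in range(100):
            n_pos = int(rng.integers(1, 6))
            h = rng.normal(size=(1, 6, width))
            mask = np.zeros((1, 6))
            mask[0, :n_pos] = 1
            t, a = fn(ad.Tensor(h), mask, p)
            scores = np.tanh(h[0] @ w + b) @ ctx[:, 0]
            e = np.exp(scores[:n_pos] - scores[:n_pos].max())
            expected_a = e / e.sum()
            np.testing.assert_allclose(a.data[0, :n_pos], expected_a, atol=1e-6)
            np.testing.assert_allclose(
                t.data[0], (expected_a[:, None] * h[0, :n_pos]).sum(0), atol=1e-6
            )


class TestSoftmaxHeads:
    def test_uniform_logits_give_half_half(self):
        p = {"W_c": ad.Tensor(np.zeros((4, 2))), "b_c": ad.Tensor(np.zeros(2))}
        out = mdl.classify_tweet(ad.Tensor(np.ones((3, 4))), p)
        np.testing.assert_allclose(out.data, 0.5)

    def test_log3_logit_gives_three_quarters(self):
        p = {"W_u": ad.Tensor(np.zeros((4, 2))),
             "b_u": ad.Tensor(np.array([np.log(3.0), 0.0]))}
        out = mdl.classify_user(ad.Tensor(np.zeros((2, 4))), p)
        np.testing.assert_allclose(out.data, [[0.75, 0.25]] * 2, atol=1e-12)

    def test_rows_sum_to_one_on_random_input(self, rng):
        p = {"W_c": ad.Tensor(rng.normal(size=(4, 2))),
             "b_c": ad.Tensor(rng.normal(size=2))}
        out = mdl.classify_tweet(ad.Tensor(rng.normal(size=(10, 4))), p)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0)


class TestUserRepresentation:
    def test_mil_elements_are_probability_pairs(self, rng):
        probs = ad.Tensor(rng.random((2, 3, 2)))
        cfg = mdl.ModelConfig(variant="mil", max_posts=3)
        rep = mdl.build_user_representation(probs, np.ones((2, 3)), cfg)
        assert rep.data.shape == (2, 3, 2)

    def test_mila_elements_concatenate_pronouns_first(self, rng):
        probs = ad.Tensor(rng.random((2, 3, 2)))
        pron = rng.random((2, 3, 7))
        cfg = mdl.ModelConfig(variant="mila", max_posts=3)
        rep = mdl.build_user_representation(probs, np.ones((2, 3)), cfg, pron)
        assert rep.data.shape == (2, 3, 9)
        np.testing.assert_allclose(rep.data[..., :7], pron)

    def test_padded_slots_are_zero(self, rng):
        probs = ad.Tensor(rng.random((1, 3, 2)))
        pron = rng.random((1, 3, 7))
        cfg = mdl.ModelConfig(variant="mila", max_posts=3)
        mask = np.array([[1, 1, 0]])
        rep = mdl.build_user_representation(probs, mask, cfg, pron)
        assert (rep.data[0, 2] == 0).all()

    def test_mila_without_pronouns_is_an_error(self, rng):
        cfg = mdl.ModelConfig(variant="mila", max_posts=3)
        with pytest.raises(ValueError, match="pronoun"):
            mdl.build_user_representation(
                ad.Tensor(rng.random((1, 3, 2))), np.ones((1, 3)), cfg
            )


class TestForwardInvariants:
    def test_attention_normalization_and_prob_simplex(self, dataset, params, config):
        """Both attention maps sum to 1 over unmasked elements; instance and
        user probabilities lie on the 2-simplex."""
        out = mdl.forward(params, dataset, config)
        np.testing.assert_allclose(out.user_probs.sum(axis=1), 1.0)
        for u in range(len(dataset)):
            np.testing.assert_allclose(out.tweet_attention[u].sum(), 1.0)
            assert (out.tweet_attention[u][dataset.post_mask[u] == 0] == 0).all()
            for j in range(dataset.token_ids.shape[1]):
                if dataset.post_mask[u, j]:
                    np.testing.assert_allclose(out.word_attention[u, j].sum(), 1.0)
                    np.testing.assert_allclose(out.instance_probs[u, j].sum(), 1.0)
                else:
                    assert (out.instance_probs[u, j] == 0).all()

    def test_eval_forward_is_deterministic(self, dataset, params, config):
        out1 = mdl.forward(params, dataset, config)
        out2 = mdl.forward(params, dataset, config)
        np.testing.assert_array_equal(out1.user_probs, out2.user_probs)
        np.testing.assert_array_equal(out1.word_attention, out2.word_attention)

    def test_padding_never_changes_outputs(self, dataset, params, config, rng):
        """Appending padded posts and padded token columns leaves every
        output on the original positions unchanged."""
        out = mdl.forward(params, dataset, config)
        extra_p, extra_t = 3, 2
        n_u, n_p, n_t = dataset.token_ids.shape
        pad = lambda a, shape: np.concatenate(
            [a, np.zeros(shape, dtype=a.dtype)], axis=1)
        ids2 = np.zeros((n_u, n_p + extra_p, n_t + extra_t), dtype=np.int64)
        tmask2 = np.zeros_like(ids2)
        ids2[:, :n_p, :n_t] = dataset.token_ids
        tmask2[:, :n_p, :n_t] = dataset.token_mask
        pmask2 = pad(dataset.post_mask, (n_u, extra_p))
        pron2 = np.concatenate(
            [dataset.pronouns, np.zeros((n_u, extra_p, 7))], axis=1)
        bigger = mdl.BagDataset(ids2, tmask2, pmask2, dataset.labels, pron2)
        cfg2 = mdl.ModelConfig(**{**config.__dict__,
                                  "max_posts": n_p + extra_p,
                                  "max_tokens": n_t + extra_t})
        out2 = mdl.forward(params, bigger, cfg2)
        np.testing.assert_allclose(out2.user_probs, out.user_probs, atol=1e-12)
        np.testing.assert_allclose(out2.tweet_attention[:, :n_p],
                                   out.tweet_attention, atol=1e-12)
        np.testing.assert_allclose(out2.word_attention[:, :n_p, :n_t],
                                   out.word_attention, atol=1e-12)
        np.testing.assert_allclose(out2.instance_probs[:, :n_p],
                                   out.instance_probs, atol=1e-12)

    def test_mila_with_zero_anaphora_weights_reduces_to_mil(self, rng):
        """Setting the user-encoder input weights of the pronoun block to
        zero and feeding zero pronoun features reproduces the MIL model."""
        mil_cfg = mdl.ModelConfig(variant="mil", embedding_dim=8,
                                  word_gru_hidden=3, user_gru_hidden=4,
                                  attention_dim=3, max_posts=5, max_tokens=6,
                                  seed=1)
        mila_cfg = mdl.ModelConfig(**{**mil_cfg.__dict__, "variant": "mila"})
        mil_params = mdl.init_params(mil_cfg, vocab_size=20)
        mila_params = {k: v.copy() for k, v in mil_params.items()}
        for prefix in ("ugru_f", "ugru_b"):
            w = np.zeros((9, mil_params[f"{prefix}/W"].shape[1]))
            w[7:] = mil_params[f"{prefix}/W"]
            mila_params[f"{prefix}/W"] = w
        data = make_random_dataset(rng, n_users=5, n_posts=5, n_tokens=6,
                                   vocab_size=20)
        data_zero_pron = mdl.BagDataset(
            data.token_ids, data.token_mask, data.post_mask, data.labels,
            np.zeros((5, 5, 7)),
        )
        out_mil = mdl.forward(mil_params, data, mil_cfg)
        out_mila = mdl.forward(mila_params, data_zero_pron, mila_cfg)
        np.testing.assert_allclose(out_mila.user_probs, out_mil.user_probs,
                                   atol=1e-12)


class TestTraining:
    def _toy_data(self, seed):
        corpus = syn.generate_corpus(syn.GeneratorConfig(
            n_positive_users=10, n_control_users=10,
            posts_per_user=syn.PostCountSpec(8, 8, 8.0), seed=seed))
        vocab = build_vocabulary(corpus)
        ids, tmask, pmask, labels, bags = encode_corpus(corpus, vocab, 8, 12)
        pron = np.stack([features_for_bag(b.tokens, max_posts=8) for b in bags])
        return mdl.BagDataset(ids, tmask, pmask, labels, pron), vocab

    def _tiny_config(self, seed=0, **kw):
        return mdl.ModelConfig(variant="mila", embedding_dim=8,
                               word_gru_hidden=3, user_gru_hidden=3,
                               attention_dim=3, max_posts=8, max_tokens=12,
                               seed=seed, **kw)

    def test_loss_decreases_on_separable_toy_corpus(self):
        data, vocab = self._toy_data(seed=5)
        cfg = self._tiny_config()
        params = mdl.init_params(cfg, len(vocab))
        fitted, history = mdl.train(
            params, data, data, cfg,
            mdl.TrainConfig(max_epochs=8, patience=8, seed=0, batch_size=8),
        )
        assert history["train_loss"][-1] < history["train_loss"][0]
        for arr in fitted.values():
            assert np.isfinite(arr).all()

    def test_same_seed_gives_identical_history(self):
        data, vocab = self._toy_data(seed=6)
        cfg = self._tiny_config()
        histories = []
        for _ in range(2):
            params = mdl.init_params(cfg, len(vocab))
            _, h = mdl.train(params, data, data, cfg,
                             mdl.TrainConfig(max_epochs=3, patience=3, seed=4,
                                             batch_size=8))
            histories.append(h)
        assert histories[0] == histories[1]

    @pytest.mark.parametrize("opt", ["adam", "adamod"])
    def test_optimizers_minimize_a_quadratic(self, opt):
        params = {"x": np.array([5.0, -3.0])}
        # beta3 shortened so the AdaMod rate bound warms up within the run
        optimizer = (mdl.Adam(lr=0.1) if opt == "adam"
                     else mdl.AdaMod(lr=0.1, beta3=0.99))
        for _ in range(400):
            optimizer.step(params, {"x": 2 * params["x"]})
        np.testing.assert_allclose(params["x"], 0.0, atol=1e-2)

    def test_adamod_bounds_early_steps_below_adam(self):
        """The moving-average rate bound makes AdaMod's first update
        strictly smaller than Adam's for identical gradients."""
        grads = {"x": np.array([4.0])}
        pa = {"x": np.array([1.0])}
        pm = {"x": np.array([1.0])}
        mdl.Adam(lr=0.1).step(pa, {k: v.copy() for k, v in grads.items()})
        mdl.AdaMod(lr=0.1).step(pm, {k: v.copy() for k, v in grads.items()})
        assert abs(1.0 - pm["x"][0]) < abs(1.0 - pa["x"][0])

    def test_divergence_aborts_with_diagnostic(self):
        data, vocab = self._toy_data(seed=7)
        cfg = self._tiny_config()
        params = mdl.init_params(cfg, len(vocab))
        params["W_u"] *= np.inf  # poison the head -> non-finite loss
        with pytest.raises(RuntimeError, match="non-finite"):
            mdl.train(params, data, data, cfg,
                      mdl.TrainConfig(max_epochs=1, seed=0))

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = self._tiny_config(seed=3)
        params = mdl.init_params(cfg, 25)
        path = tmp_path / "model.ckpt.npz"
        mdl.save_checkpoint(path, params, cfg)
        loaded, loaded_cfg = mdl.load_checkpoint(path)
        assert loaded_cfg == cfg
        assert set(loaded) == set(params)
        for k in params:
            np.testing.assert_array_equal(loaded[k], params[k])


class TestInstanceOrientation:
    def test_flipped_head_is_reoriented(self, rng):
        """If class 0 of the instance head behaves as the positive class,
        orientation picks column 0."""
        n_u, n_p = 6, 4
        pmask = np.ones((n_u, n_p))
        yhat = np.array([1, 1, 1, 0, 0, 0])
        p1 = rng.random((n_u, n_p)) * 0.2
        p1[:3] += 0.7  # predicted positives have high column-0 scores
        probs = np.stack([p1, 1 - p1], axis=-1)
        scores, cls = mdl.oriented_instance_scores(probs, pmask, yhat)
        assert cls == 0
        np.testing.assert_allclose(scores, p1)

    def test_correctly_ordered_head_keeps_class_one(self, rng):
        n_u, n_p = 6, 4
        pmask = np.ones((n_u, n_p))
        yhat = np.array([1, 1, 1, 0, 0, 0])
        p1 = rng.random((n_u, n_p)) * 0.2
        p1[:3] += 0.7
        probs = np.stack([1 - p1, p1], axis=-1)
        scores, cls = mdl.oriented_instance_scores(probs, pmask, yhat)
        assert cls == 1
        np.testing.assert_allclose(scores, p1)

    def test_count_params_excludes_frozen_embeddings(self):
        cfg = mdl.ModelConfig(variant="mil", embedding_dim=4, word_gru_hidden=2,
                              user_gru_hidden=2, attention_dim=2, max_posts=3,
                              max_tokens=4)
        params = mdl.init_params(cfg, vocab_size=10)
        k_all = mdl.count_params(params, cfg)
        frozen_cfg = mdl.ModelConfig(**{**cfg.__dict__, "freeze_embeddings": True})
        assert k_all - mdl.count_params(params, frozen_cfg) == 10 * 4
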