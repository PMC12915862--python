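import numpy as np
import pytest

from capreg.model_core import (
    AttentionWeights,
    LlamaModel,
    LoraLinear,
    MlpWeights,
    ModelConfig,
    apply_rope,
    attention,
    causal_lm_loss,
    causal_lm_loss_and_grad,
    classification_loss,
    classification_loss_and_grad,
    llama_mlp,
    lora_forward,
    lora_init,
    lora_merge,
    rope_angles,
)


@pytest.fixture
def config():
    return ModelConfig(
        vocab_size=11, d_model=8, n_heads=2, n_kv_groups=2, n_layers=2,
        d_ff=16, max_positions=64,
    )


class TestRope:
    def test_theta_zero_is_one(self, config):
        assert rope_angles(config).theta[0] == 1.0

    def test_theta_closed_form_d4(self):
        cfg = ModelConfig(vocab_size=4, d_model=8, n_heads=2, n_kv_groups=2)
        # head_dim = 4 -> theta_1 = 10000^(-2/4) = 0.01
        theta = rope_angles(cfg).theta
        assert theta[1] == pytest.approx(10_000 ** (-0.5))
        assert theta[1] == pytest.approx(0.01)

    def test_theta_strictly_decreasing(self):
        cfg = ModelConfig(vocab_size=4, d_model=64, n_heads=2, n_kv_groups=2)
        theta = rope_angles(cfg).theta
        assert np.all(np.diff(theta) < 0)

    def test_identity_at_position_zero(self, config, rng):
        cache = rope_angles(config)
        v = rng.normal(size=config.head_dim)
        assert np.allclose(apply_rope(v, 0, cache), v)

    def test_norm_preserved(self, config, rng):
        cache = rope_angles(config)
        for _ in range(20):
            v = rng.normal(size=config.head_dim)
            p = int(rng.integers(0, 60))
            assert np.linalg.norm(apply_rope(v, p, cache)) == pytest.approx(
                np.linalg.norm(v), abs=1e-6
            )

    def test_dot_product_depends_only_on_relative_position(self, config, rng):
        cache = rope_angles(config)
        q = rng.normal(size=config.head_dim)
        k = rng.normal(size=config.head_dim)
        d1 = apply_rope(q, 5, cache) @ apply_rope(k, 3, cache)
        d2 = apply_rope(q, 7, cache) @ apply_rope(k, 5, cache)
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_length_mismatch_rejected(self, config):
        with pytest.raises(ValueError):
            apply_rope(np.ones(5), 0, rope_angles(config))


def _attn_weights(rng, d, H, G, hd):
    return AttentionWeights(
        W_q=rng.normal(size=(d, H * hd)),
        W_k=rng.normal(size=(d, G * hd)),
        W_v=rng.normal(size=(d, G * hd)),
        W_o=rng.normal(size=(H * hd, d)),
        n_heads=H,
        n_kv_groups=G,
    )


class TestAttention:
    def test_single_token_passes_value_through(self, config, rng):
        w = _attn_weights(rng, 8, 2, 2, 4)
        cache = rope_angles(config)
        x = rng.normal(size=(1, 8))
        out, probs = attention(x, w, cache)
        assert probs.shape == (2, 1, 1)
        assert np.allclose(probs, 1.0)
        expected = (x @ w.W_v) @ w.W_o  # softmax of one logit is 1
        assert np.allclose(out, expected, atol=1e-9)

    def test_rows_sum_to_one(self, config, rng):
        w = _attn_weights(rng, 8, 2, 2, 4)
        x = rng.normal(size=(3, 10, 8))
        _, probs = attention(x, w, rope_angles(config), valid_len=np.array([10, 7, 5]))
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_group_sharing_equivalence(self, config, rng):
        """n_kv_groups=1 with duplicated K/V projections equals n_kv_groups=2."""
        hd = 4
        shared_k = rng.normal(size=(8, hd))
        shared_v = rng.normal(size=(8, hd))
        wq = rng.normal(size=(8, 2 * hd))
        wo = rng.normal(size=(2 * hd, 8))
        grouped = AttentionWeights(wq, shared_k, shared_v, wo, n_heads=2, n_kv_groups=1)
        tiled = AttentionWeights(
            wq, np.hstack([shared_k, shared_k]), np.hstack([shared_v, shared_v]),
            wo, n_heads=2, n_kv_groups=2,
        )
        x = rng.normal(size=(2, 6, 8))
        cache = rope_angles(config)
        out_a, _ = attention(x, grouped, cache)
        out_b, _ = attention(x, tiled, cache)
        assert np.allclose(out_a, out_b, atol=1e-6)

    def test_causal_mask_blocks_future(self, config, rng):
        w = _attn_weights(rng, 8, 2, 2, 4)
        x = rng.normal(size=(1, 6, 8))
        _, probs = attention(x, w, rope_angles(config))
        assert np.allclose(np.triu(probs[0, 0], k=1), 0.0)


class TestLlamaMlp:
    def test_zero_input_zero_output(self, rng):
        w = MlpWeights(rng.normal(size=(4, 9)), rng.normal(size=(4, 9)), rng.normal(size=(9, 4)))
        assert np.allclose(llama_mlp(np.zeros((3, 4)), w), 0.0)

    def test_matches_hand_composed_expression(self, rng):
        w = MlpWeights(rng.normal(size=(4, 9)), rng.normal(size=(4, 9)), rng.normal(size=(9, 4)))
        x = rng.normal(size=(3, 4))
        g = x @ w.W_gate
        silu = g / (1 + np.exp(-g))
        expected = (silu * (x @ w.W_up)) @ w.W_down
        assert np.allclose(llama_mlp(x, w), expected, atol=1e-6)

    def test_linear_in_down_projection(self, rng):
        w = MlpWeights(rng.normal(size=(4, 9)), rng.normal(size=(4, 9)), rng.normal(size=(9, 4)))
        w2 = MlpWeights(w.W_gate, w.W_up, 2 * w.W_down)
        x = rng.normal(size=(2, 4))
        assert np.allclose(2 * llama_mlp(x, w), llama_mlp(x, w2))


class TestLora:
    def test_zero_b_gives_base_function_exactly(self, rng):
        lin = LoraLinear(6, 5, rng)
        x = rng.normal(size=(4, 6))
        y_base = lin.forward(x)
        lin.enable_lora(2, 4.0, rng)
        assert np.array_equal(lin.forward(x), y_base)

    def test_explicit_2x2_effective_weight(self, rng):
        lin = LoraLinear(2, 2, rng)
        lin.W.data = np.eye(2)
        lin.enable_lora(1, 1.0, rng)  # scale = alpha/r = 1
        lin.A.data = np.array([[1.0], [0.0]])
        lin.B.data = np.array([[0.0, 1.0]])
        assert np.allclose(lora_merge(lin), [[1.0, 1.0], [0.0, 1.0]])

    def test_forward_equals_merged_weight(self, rng):
        lin = LoraLinear(6, 5, rng)
        lin.enable_lora(2, 4.0, rng)
        lin.B.data = rng.normal(size=lin.B.data.shape)
        x = rng.normal(size=(7, 6))
        assert np.allclose(lora_forward(x, lin), x @ lora_merge(lin), atol=1e-6)

    def test_kaiming_init_properties(self, rng):
        lin = LoraLinear(6, 5, rng)
        lin.enable_lora(3, 6.0, rng)
        lora_init(lin, np.random.default_rng(9))
        assert np.all(lin.B.data == 0.0)
        assert np.count_nonzero(lin.A.data) == lin.A.data.size

    def test_init_deterministic_under_seed(self, rng):
        lin = LoraLinear(6, 5, rng)
        lin.enable_lora(3, 6.0, rng)
        lora_init(lin, np.random.default_rng(3))
        a1 = lin.A.data.copy()
        lora_init(lin, np.random.default_rng(3))
        assert np.array_equal(lin.A.data, a1)

    def test_merge_then_reinit_preserves_function(self, rng):
        lin = LoraLinear(6, 5, rng)
        lin.enable_lora(2, 4.0, rng)
        lin.B.data = rng.normal(size=lin.B.data.shape)
        x = rng.normal(size=(4, 6))
        before = lin.forward(x)
        lin.merge_adapters()
        lin.reinit_adapters(np.random.default_rng(11))
        assert np.allclose(lin.forward(x), before, atol=1e-6)

    def test_oversized_rank_warns(self, rng):
        lin = LoraLinear(4, 4, rng)
        with pytest.warns(UserWarning, match="no longer low-rank"):
            lin.enable_lora(4, 8.0, rng)


class TestFullModel:
    def test_causality_probe(self, config, rng):
        """Changing a future input never alters logits at earlier positions."""
        model = LlamaModel(config, seed=0)
        ids = rng.integers(0, 11, size=(1, 8))
        logits = model.forward_lm(ids)
        mutated = ids.copy()
        mutated[0, 6] = (mutated[0, 6] + 1) % 11
        logits2 = model.forward_lm(mutated)
        assert np.allclose(logits[0, :6], logits2[0, :6], atol=1e-12)
        assert not np.allclose(logits[0, 6:], logits2[0, 6:])

    def test_initial_lm_loss_near_log_vocab(self, rng):
        # sanity: an untrained model is close to the uniform-prediction
        # loss ln V (not exactly at it: the head starts at standard scale)
        cfg = ModelConfig(vocab_size=101, d_model=16, n_heads=2, n_kv_groups=2, n_layers=2)
        model = LlamaModel(cfg, seed=0)
        ids = rng.integers(0, 101, size=(4, 32))
        loss = causal_lm_loss(model.forward_lm(ids), ids)
        assert loss == pytest.approx(np.log(101), rel=0.15)

    def test_gradients_match_finite_differences(self, config, rng):
        model = LlamaModel(config, seed=3)
        ids = rng.integers(0, 11, size=(2, 5))
        lens = np.array([5, 3])
        labels = np.array([1, 0])
        model.zero_grad()
        loss, dl = classification_loss_and_grad(model.forward_cls(ids, lens), labels)
        model.backward_cls(dl)
        eps = 1e-6
        for name, p in model.params():
            if name.startswith("lm_head"):
                continue
            flat, grad = p.data.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                up = classification_loss(model.forward_cls(ids, lens), labels)
                flat[i] = old - eps
                dn = classification_loss(model.forward_cls(ids, lens), labels)
                flat[i] = old
                num = (up - dn) / (2 * eps)
                assert num == pytest.approx(grad[i], abs=1e-6), name

    def test_checkpoint_round_trip_with_adapters(self, config, rng, tmp_path):
        model = LlamaModel(config, seed=4)
        model.enable_lora(2, 4.0, np.random.default_rng(1))
        for lin in model.lora_linears():
            lin.B.data = rng.normal(size=lin.B.data.shape)
        ids = rng.integers(0, 11, size=(2, 6))
        before = model.forward_lm(ids)
        model.save(tmp_path / "ckpt")
        loaded = LlamaModel.load(tmp_path / "ckpt")
        assert np.allclose(loaded.forward_lm(ids), before, atol=1e-12)


class TestLosses:
    def test_uniform_logits_give_log_vocab(self):
        logits = np.zeros((2, 5, 4))
        ids = np.zeros((2, 5), dtype=int)
        assert causal_lm_loss(logits, ids) == pytest.approx(np.log(4), abs=1e-6)

    def test_loss_decreases_as_true_logit_grows(self):
        ids = np.array([[0, 1]])
        losses = []
        for z in (0.0, 2.0, 10.0, 50.0):
            logits = np.zeros((1, 2, 4))
            logits[0, 0, 1] = z
            losses.append(causal_lm_loss(logits, ids))
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-10

    def test_matches_independent_logsumexp_reference(self, rng):
        logits = rng.normal(size=(2, 5, 7)) * 3
        ids = rng.integers(0, 7, size=(2, 5))
        from scipy.special import logsumexp

        ref = []
        for b in range(2):
            for t in range(4):
                y = ids[b, t + 1]
                z = logits[b, t]
                ref.append(logsumexp(z) - z[y])
        assert causal_lm_loss(logits, ids) == pytest.approx(np.mean(ref), abs=1e-6)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            causal_lm_loss(np.zeros((1, 1, 4)), np.zeros((1, 1), dtype=int))

    def test_symmetric_logits_give_log_two(self):
        assert classification_loss(np.zeros((3, 2)), np.array([0, 1, 1])) == pytest.approx(
            np.log(2), abs=1e-6
        )

    def test_confident_correct_logit(self):
        loss = classification_loss(np.array([[0.0, 10.0]]), np.array([1]))
        assert loss == pytest.approx(np.log(1 + np.exp(-10)), abs=1e-9)
        assert loss == pytest.approx(4.5399e-5, rel=1e-3)

    def test_batch_mean_equals_mean_of_singletons(self, rng):
        logits = rng.normal(size=(6, 2))
        labels = rng.integers(0, 2, size=6)
        per = [
            classification_loss(logits[i : i + 1], labels[i : i + 1]) for i in range(6)
        ]
        assert classification_loss(logits, labels) == pytest.approx(np.mean(per))

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.zeros((1, 2)), np.array([2]))

    def test_lm_grad_matches_reference(self, rng):
        logits = rng.normal(size=(2, 4, 5))
        ids = rng.integers(0, 5, size=(2, 4))
        _, grad = causal_lm_loss_and_grad(logits, ids)
        eps = 1e-6
        i = (1, 2, 3)
        up = logits.copy(); up[i] += eps
        dn = logits.copy(); dn[i] -= eps
        num = (causal_lm_loss(up, ids) - causal_lm_loss(dn, ids)) / (2 * eps)
        assert grad[i] == pytest.approx(num, abs=1e-6)
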