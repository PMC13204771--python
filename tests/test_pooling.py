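"""Learnable-query attention pooling, ablation baselines, classifier head."""

import numpy as np
import pytest

from lungrg.nn import Tensor, cross_entropy_logits
from lungrg.pooling import (ClassifierHead, LatentPoolConfig, LQAPBlock,
                            SingleHeadAttentionPool, baseline_pool,
                            concat_slices, latent_pool_config,
                            patient_pool_config, prediction_from_logits)

RNG = np.random.default_rng(0)
SMALL = LatentPoolConfig(n_latent=5, embed_dim=64, heads=2)


@pytest.fixture()
def small_pool():
    return LQAPBlock(SMALL, np.random.default_rng(1)).eval()


class TestConcat:
    def test_five_sequences_concatenate_in_order(self):
        parts = [Tensor(np.full((4, 8), i, dtype=float)) for i in range(5)]
        out = concat_slices(parts)
        assert out.shape == (20, 8)
        assert (out.data[0] == 0).all() and (out.data[-1] == 4).all()

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            concat_slices([Tensor(np.zeros((4, 8)))] * 3)

    def test_width_mismatch_rejected(self):
        parts = [Tensor(np.zeros((4, 8)))] * 4 + [Tensor(np.zeros((4, 6)))]
        with pytest.raises(ValueError):
            concat_slices(parts)


class TestLQAP:
    def test_output_rows_equal_n_latent(self, small_pool):
        for n_tokens in (15, 25, 35):  # M = 3, 5, 7 slice blocks
            z = small_pool(Tensor(RNG.normal(size=(n_tokens, 64))))
            assert z.shape == (5, 64)

    def test_slice_permutation_invariance(self, small_pool):
        blocks = [Tensor(RNG.normal(size=(5, 64))) for _ in range(5)]
        z1 = small_pool(concat_slices(blocks)).data
        perm = [blocks[i] for i in (4, 2, 0, 3, 1)]
        z2 = small_pool(concat_slices(perm)).data
        assert np.abs(z1 - z2).max() <= 1e-5

    def test_constant_values_give_identical_attention_rows(self, small_pool):
        v = RNG.normal(size=64)
        tokens = Tensor(np.tile(v, (20, 1)))
        z_prime_minus_q = small_pool.attn(
            small_pool.ln_q(small_pool.queries),
            small_pool.ln_k(tokens), small_pool.ln_v(tokens))[0].data
        assert np.allclose(z_prime_minus_q, z_prime_minus_q[0], atol=1e-10)

    def test_nonfinite_input_rejected(self, small_pool):
        bad = np.zeros((10, 64))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            small_pool(Tensor(bad))

    def test_width_mismatch_rejected(self, small_pool):
        with pytest.raises(ValueError):
            small_pool(Tensor(np.zeros((10, 32))))

    def test_closed_form_counts(self):
        lat = LQAPBlock(latent_pool_config(), np.random.default_rng(0))
        pat = LQAPBlock(patient_pool_config(), np.random.default_rng(0))
        assert lat.n_parameters() == lat.expected_parameter_count()
        assert pat.n_parameters() == pat.expected_parameter_count()

    def test_residual_adds_raw_queries(self, small_pool):
        # zeroing the attention output projection leaves z' == queries
        small_pool.attn.wo.weight.data[...] = 0.0
        small_pool.attn.wo.bias.data[...] = 0.0
        tokens = Tensor(RNG.normal(size=(10, 64)))
        attn_out, _ = small_pool.attn(
            small_pool.ln_q(small_pool.queries),
            small_pool.ln_k(tokens), small_pool.ln_v(tokens))
        z_prime = (attn_out + small_pool.queries).data
        assert np.allclose(z_prime, small_pool.queries.data)


class TestBaselinePools:
    def test_mean_of_identical_tokens(self):
        v = RNG.normal(size=8)
        out = baseline_pool(Tensor(np.tile(v, (12, 1))), "mean")
        assert np.allclose(out.data, v)

    def test_max_dominates_mean_elementwise(self):
        tokens = Tensor(RNG.normal(size=(30, 8)))
        mx = baseline_pool(tokens, "max").data
        mn = baseline_pool(tokens, "mean").data
        assert (mx >= mn - 1e-12).all()

    def test_uniform_single_head_equals_mean(self):
        pool = SingleHeadAttentionPool(8, np.random.default_rng(2))
        pool.query.data[...] = 0.0  # zero query -> uniform softmax
        tokens = Tensor(RNG.normal(size=(30, 8)))
        out = baseline_pool(tokens, "single_head_attn", pool_module=pool)
        assert np.allclose(out.data, tokens.data.mean(axis=0))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            baseline_pool(Tensor(np.zeros((5, 8))), "median")


class TestClassification:
    def test_uniform_logits_give_uniform_probabilities_and_ln3_loss(self):
        pred = prediction_from_logits(np.zeros(3))
        assert np.allclose(pred.probabilities, 1 / 3)
        loss = cross_entropy_logits(Tensor(np.zeros((1, 3))), np.array([1]))
        assert np.isclose(loss.item(), np.log(3))

    def test_probabilities_sum_to_one(self):
        for _ in range(5):
            pred = prediction_from_logits(RNG.normal(size=3) * 10)
            assert np.isclose(pred.probabilities.sum(), 1.0)
            assert np.isclose(pred.max_confidence,
                              pred.probabilities.max())

    def test_confident_correct_prediction_has_near_zero_loss(self):
        logits = Tensor(np.array([[50.0, 0.0, 0.0]]))
        loss = cross_entropy_logits(logits, np.array([0]))
        assert loss.item() < 1e-8

    def test_head_output_is_three_logits(self):
        head = ClassifierHead(64, 32, rng=np.random.default_rng(3)).eval()
        out = head(Tensor(RNG.normal(size=64)))
        assert out.shape == (3,)
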