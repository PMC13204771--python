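"""Cross-attention text decoder: causality, tying, generation, loading."""

import numpy as np
import pytest

from lungrg.decoder import DecoderConfig, TINY_DECODER, TextDecoder
from lungrg.nn import Tensor

CTX = Tensor(np.random.default_rng(0).normal(size=(5, 64)))


@pytest.fixture()
def decoder():
    return TextDecoder(TINY_DECODER, np.random.default_rng(1)).eval()


class TestTeacherForcing:
    def test_logit_shape_covers_vocabulary(self, decoder):
        ids = np.array([511, 5, 9, 3, 511])
        logits, loss = decoder.decode_teacher_forced(ids, CTX)
        assert logits.shape == (4, TINY_DECODER.vocab)
        assert np.isfinite(loss.item())

    def test_future_tokens_cannot_influence_past_logits(self, decoder):
        a, _ = decoder.forward(np.array([511, 1, 2, 3, 4]), CTX)
        b, _ = decoder.forward(np.array([511, 1, 2, 99, 100]), CTX)
        assert np.allclose(a.data[:3], b.data[:3])
        assert not np.allclose(a.data[3:], b.data[3:])

    def test_loss_mask_excludes_padding(self, decoder):
        ids = np.array([511, 5, 9, 0, 0])
        m_all = np.ones(5)
        m_pad = np.array([1, 1, 1, 0, 0])
        _, l_all = decoder.decode_teacher_forced(ids, CTX, loss_mask=m_all)
        _, l_pad = decoder.decode_teacher_forced(ids, CTX, loss_mask=m_pad)
        assert not np.isclose(l_all.item(), l_pad.item())

    def test_context_width_mismatch_rejected(self, decoder):
        with pytest.raises(ValueError):
            decoder.forward(np.array([511, 1]),
                            Tensor(np.zeros((5, 32))))

    def test_out_of_vocab_token_rejected(self, decoder):
        with pytest.raises(ValueError):
            decoder.forward(np.array([512]), CTX)


class TestCrossAttention:
    def test_rows_sum_to_one_over_context_tokens(self, decoder):
        _, cross = decoder.forward(np.array([511, 1, 2]), CTX,
                                   collect_cross_attn=True)
        assert len(cross) == TINY_DECODER.layers
        for probs in cross:
            assert probs.shape[-1] == CTX.shape[0]
            assert np.allclose(probs.data.sum(-1), 1.0, atol=1e-6)


class TestWeightTying:
    def test_head_and_embedding_share_storage(self, decoder):
        assert decoder.lm_head_weight is decoder.tok_emb.weight

    def test_mutating_embedding_changes_head_outputs(self, decoder):
        ids = np.array([511, 7])
        before, _ = decoder.forward(ids, CTX)
        decoder.tok_emb.weight.data[123] += \
            np.linspace(-5.0, 5.0, TINY_DECODER.embed_dim)
        after, _ = decoder.forward(ids, CTX)
        assert not np.allclose(before.data[:, 123], after.data[:, 123])


class TestGeneration:
    def test_length_bounded_by_max_generate(self, decoder):
        out = decoder.generate(CTX)
        assert out.size <= TINY_DECODER.max_generate

    def test_greedy_is_deterministic(self, decoder):
        a = decoder.generate(CTX, max_new=12)
        b = decoder.generate(CTX, max_new=12)
        assert np.array_equal(a, b)

    def test_greedy_prefix_stable_under_longer_budget(self, decoder):
        short = decoder.generate(CTX, max_new=6)
        long = decoder.generate(CTX, max_new=16)
        assert np.array_equal(long[:short.size], short)


class TestParameterCount:
    def test_closed_form_matches_instantiated(self, decoder):
        assert decoder.n_parameters() == decoder.expected_parameter_count()

    def test_tied_head_not_double_counted(self, decoder):
        names = [n for n, _ in decoder.named_parameters()]
        assert sum(n.endswith("tok_emb.weight") for n in names) == 1
        assert not any("lm_head" in n for n in names)


class TestPretrainedLoading:
    def _mini_checkpoint(self, decoder, tmp_path):
        state = {"tok_emb.weight": np.ones_like(decoder.tok_emb.weight.data),
                 "pos_emb.weight": np.zeros((7, 7)),  # wrong shape
                 "block0.self_attn.wq.weight":
                     np.ones_like(decoder.blocks[0].self_attn.wq.weight.data),
                 "block0.cross_attn.wq.weight":
                     np.ones_like(decoder.blocks[0].cross_attn.wq.weight.data)}
        path = tmp_path / "mini_gpt_synthetic.npz"
        np.savez(path, **state)
        return str(path)

    def test_shape_matching_tensors_copied(self, decoder, tmp_path):
        report = decoder.load_pretrained_lm(
            self._mini_checkpoint(decoder, tmp_path))
        assert "tok_emb.weight" in report["copied"]
        assert "block0.self_attn.wq.weight" in report["copied"]
        assert "pos_emb.weight" in report["fresh"]  # shape mismatch
        assert (decoder.tok_emb.weight.data == 1.0).all()

    def test_cross_attention_always_fresh(self, decoder, tmp_path):
        report = decoder.load_pretrained_lm(
            self._mini_checkpoint(decoder, tmp_path))
        assert all(".cross_attn." not in n for n in report["copied"])
        assert any(".cross_attn." in n for n in report["fresh"])

    def test_missing_checkpoint_raises(self, decoder):
        with pytest.raises(FileNotFoundError):
            decoder.load_pretrained_lm("/nonexistent/ckpt.npz")


def test_full_size_config_contract():
    cfg = DecoderConfig()
    assert cfg.vocab == 50_257 and cfg.max_positions == 1024
    assert cfg.bos_id == cfg.eos_id == 50_256
    with pytest.raises(ValueError):
        DecoderConfig(max_generate=2048)
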