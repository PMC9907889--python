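"""Prefix-augmented attention, subword pooling and the BiLSTM contextualizer."""

import numpy as np
import pytest

from gridner._autodiff import Tensor
from gridner._nn import AdamW, Linear
from gridner.corpus_io import LabeledSentence, build_subword_alignment
from gridner.model import make_batch
from gridner.prefix_encoder import (
    BiLSTM,
    EncoderConfig,
    PrefixTransformerEncoder,
    init_prefix_bank,
    pool_subwords,
    prefix_self_attention,
)


def _attention_setup(rng, L=4, d=8, heads=2, P=3, B=1):
    H = Tensor(rng.normal(size=(B, L, d)), requires_grad=True)
    wq, wk, wv = (Linear(d, d, rng) for _ in range(3))
    config = EncoderConfig(layers=1, heads=heads, hidden_dim=d, prefix_length=P,
                           word_dim=d)
    bank = init_prefix_bank(config, seed=0)
    mask = np.ones((B, L))
    return H, wq, wk, wv, bank, mask


class TestPrefixAttention:
    def test_rows_sum_to_one_over_unmasked_columns(self):
        rng = np.random.default_rng(0)
        H, wq, wk, wv, bank, mask = _attention_setup(rng, L=5, P=4)
        mask[0, 3:] = 0.0
        _, attn = prefix_self_attention(H, wq, wk, wv, bank.keys[0], bank.values[0],
                                        2, mask)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-5)
        # masked key columns carry zero weight; prefix columns do not
        assert np.allclose(attn.data[..., 3:5], 0.0)
        assert attn.data[..., 5:].sum() > 0

    def test_map_shape_is_L_by_L_plus_P(self):
        rng = np.random.default_rng(1)
        H, wq, wk, wv, bank, mask = _attention_setup(rng, L=4, d=8, heads=2, P=3)
        _, attn = prefix_self_attention(H, wq, wk, wv, bank.keys[0], bank.values[0],
                                        2, mask)
        assert attn.shape == (1, 2, 4, 7)

    def test_p0_reduces_to_standard_attention(self):
        """With an empty prefix the layer equals textbook scaled dot-product
        attention computed independently in NumPy."""
        rng = np.random.default_rng(2)
        H, wq, wk, wv, _, mask = _attention_setup(rng, L=6, d=8, heads=2, P=0)
        config = EncoderConfig(layers=1, heads=2, hidden_dim=8, prefix_length=0,
                               word_dim=8)
        bank = init_prefix_bank(config, seed=0)
        ctx, attn = prefix_self_attention(H, wq, wk, wv, bank.keys[0],
                                          bank.values[0], 2, mask)
        # reference: plain softmax(QK^T/sqrt(dh))V per head
        h, dh = 2, 4
        Q = (H.data @ wq.weight.data + wq.bias.data).reshape(1, 6, h, dh)
        K = (H.data @ wk.weight.data + wk.bias.data).reshape(1, 6, h, dh)
        V = (H.data @ wv.weight.data + wv.bias.data).reshape(1, 6, h, dh)
        Q, K, V = (m.transpose(0, 2, 1, 3) for m in (Q, K, V))
        logits = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(dh)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        ref_attn = e / e.sum(axis=-1, keepdims=True)
        ref_ctx = (ref_attn @ V).transpose(0, 2, 1, 3).reshape(1, 6, 8)
        assert np.allclose(attn.data, ref_attn, atol=1e-6)
        assert np.allclose(ctx.data, ref_ctx, atol=1e-6)

    def test_uniform_logits_give_uniform_weights(self):
        """Zero hidden states with zero query projection -> all logits equal,
        so every weight is 1/(L+P)."""
        rng = np.random.default_rng(3)
        H, wq, wk, wv, bank, mask = _attention_setup(rng, L=3, P=2)
        wq.weight.data[:] = 0.0
        wq.bias.data[:] = 0.0
        _, attn = prefix_self_attention(H, wq, wk, wv, bank.keys[0], bank.values[0],
                                        2, mask)
        assert np.allclose(attn.data, 1.0 / 5.0, atol=1e-12)

    def test_two_option_softmax_hand_value(self):
        """logits [0, ln 3] -> weights [0.25, 0.75]."""
        t = Tensor(np.array([[0.0, np.log(3.0)]]))
        assert np.allclose(t.softmax().data, [[0.25, 0.75]], atol=1e-12)

    def test_outputs_are_convex_combinations_of_values(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            H, wq, wk, wv, bank, mask = _attention_setup(rng, L=4, d=8, P=3)
            _, attn = prefix_self_attention(H, wq, wk, wv, bank.keys[0],
                                            bank.values[0], 2, mask)
            V = (H.data @ wv.weight.data + wv.bias.data).reshape(1, 4, 2, 4)
            V = V.transpose(0, 2, 1, 3)
            phi_v = bank.values[0].data.reshape(3, 2, 4).transpose(1, 0, 2)[None]
            V_full = np.concatenate([V, np.broadcast_to(phi_v, (1, 2, 3, 4))], axis=2)
            out = attn.data @ V_full
            lo = V_full.min(axis=2, keepdims=True) - 1e-9
            hi = V_full.max(axis=2, keepdims=True) + 1e-9
            assert (out >= lo).all() and (out <= hi).all()


class TestPrefixBank:
    def test_deterministic_given_seed(self, toy_encoder_config):
        b1 = init_prefix_bank(toy_encoder_config, seed=7)
        b2 = init_prefix_bank(toy_encoder_config, seed=7)
        for k1, k2 in zip(b1.keys, b2.keys):
            assert (k1.data == k2.data).all()

    def test_layers_are_independent(self, toy_encoder_config):
        bank = init_prefix_bank(toy_encoder_config, seed=7)
        assert len(bank.keys) == toy_encoder_config.layers
        assert not (bank.keys[0].data == bank.keys[1].data).all()

    def test_zero_length_prefix_allowed(self):
        config = EncoderConfig(layers=2, heads=2, hidden_dim=8, prefix_length=0,
                               word_dim=8)
        bank = init_prefix_bank(config, seed=0)
        assert bank.keys[0].shape == (0, 8)


class TestEncoder:
    def test_stack_shapes_and_determinism(self, toy_encoder_config,
                                          small_tokenizer, small_corpus):
        toy_encoder_config.vocab_size = len(small_tokenizer)
        enc = PrefixTransformerEncoder(toy_encoder_config, seed=0)
        batch = make_batch(small_corpus[:3], small_tokenizer)
        states1, stack1 = enc(batch.piece_ids, batch.piece_mask)
        states2, stack2 = enc(batch.piece_ids, batch.piece_mask)
        B, L = batch.piece_ids.shape
        n_guided = len(toy_encoder_config.guided_layers)
        assert stack1.maps.shape == (B, n_guided * 2, L, L + 2)
        assert states1.shape == (B, L, toy_encoder_config.hidden_dim)
        assert (states1.data == states2.data).all()

    def test_guided_last_layer_only(self, small_tokenizer, small_corpus):
        config = EncoderConfig(layers=2, heads=2, hidden_dim=16, prefix_length=2,
                               word_dim=16, guided_layers=(2,),
                               vocab_size=len(small_tokenizer))
        enc = PrefixTransformerEncoder(config, seed=0)
        batch = make_batch(small_corpus[:2], small_tokenizer)
        _, stack = enc(batch.piece_ids, batch.piece_mask)
        assert stack.maps.shape[1] == config.heads

    def test_overlong_sequence_is_hard_error(self, small_tokenizer):
        config = EncoderConfig(layers=1, heads=2, hidden_dim=16, prefix_length=2,
                               word_dim=16, max_positions=4,
                               vocab_size=len(small_tokenizer))
        enc = PrefixTransformerEncoder(config, seed=0)
        ids = np.zeros((1, 9), dtype=np.intp)
        with pytest.raises(ValueError, match="truncate"):
            enc(ids, np.ones((1, 9)))

    def test_gradient_flows_to_prefix_but_not_frozen_backbone(
        self, toy_encoder_config, small_tokenizer, small_corpus
    ):
        toy_encoder_config.vocab_size = len(small_tokenizer)
        enc = PrefixTransformerEncoder(toy_encoder_config, seed=0)
        batch = make_batch(small_corpus[:2], small_tokenizer)
        prefix_params = [p for layer in (enc.prefix.keys, enc.prefix.values)
                        for p in layer]
        backbone = [enc.layers[0].wq.weight, enc.layers[0].wk.weight,
                    enc.layers[0].wv.weight]
        before_prefix = [p.data.copy() for p in prefix_params]
        before_backbone = [p.data.copy() for p in backbone]
        states, stack = enc(batch.piece_ids, batch.piece_mask)
        loss = (stack.maps * stack.maps).sum() + (states**2).mean()
        loss.backward()
        opt = AdamW(prefix_params, lr=1e-2)  # frozen backbone: only prefixes step
        opt.step()
        assert any((p.data != b).any() for p, b in zip(prefix_params, before_prefix))
        assert all((p.data == b).all() for p, b in zip(backbone, before_backbone))
        assert all(p.grad is not None for p in backbone)  # grads do reach it


class TestPooling:
    def test_single_piece_words_identity(self, small_tokenizer):
        sent = LabeledSentence(["ab"], set())
        tok = small_tokenizer
        batch = make_batch([sent], tok)
        rng = np.random.default_rng(0)
        states = Tensor(rng.normal(size=(1, batch.piece_ids.shape[1], 4)),
                        requires_grad=True)
        lo, hi = batch.alignments[0].ranges[0]
        if lo == hi:  # single piece
            out = pool_subwords(states, batch.alignments, batch.n_words, "max")
            assert np.allclose(out.data[0, 0], states.data[0, lo])

    def test_elementwise_max_by_hand(self):
        from gridner.corpus_io import SubwordAlignment

        al = SubwordAlignment(piece_ids=[0, 5, 6, 1], ranges=[(1, 2)], n_pieces=4)
        states = Tensor(np.array([[[9.0, 9.0], [1.0, 3.0], [2.0, 0.0], [9.0, 9.0]]]),
                        requires_grad=True)
        out = pool_subwords(states, [al], np.array([1]), "max")
        assert np.allclose(out.data[0, 0], [2.0, 3.0])
        out.sum().backward()
        # gradient routes to the argmax piece per coordinate, not to specials
        assert np.allclose(states.grad[0, 1], [0.0, 1.0])
        assert np.allclose(states.grad[0, 2], [1.0, 0.0])
        assert np.allclose(states.grad[0, 0], 0.0)

    def test_mean_pooling(self):
        from gridner.corpus_io import SubwordAlignment

        al = SubwordAlignment(piece_ids=[0, 5, 6, 1], ranges=[(1, 2)], n_pieces=4)
        states = Tensor(np.array([[[0.0, 0.0], [1.0, 3.0], [3.0, 1.0], [0.0, 0.0]]]))
        out = pool_subwords(states, [al], np.array([1]), "mean")
        assert np.allclose(out.data[0, 0], [2.0, 2.0])


class TestBiLSTM:
    def test_output_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        lstm = BiLSTM(6, 8, rng)
        x = Tensor(rng.normal(size=(2, 5, 6)))
        mask = np.ones((2, 5))
        y1, y2 = lstm(x, mask), lstm(x, mask)
        assert y1.shape == (2, 5, 8)
        assert (y1.data == y2.data).all()

    def test_single_step_sequence(self):
        rng = np.random.default_rng(1)
        lstm = BiLSTM(4, 6, rng)
        y = lstm(Tensor(rng.normal(size=(1, 1, 4))), np.ones((1, 1)))
        assert y.shape == (1, 1, 6)
        assert np.isfinite(y.data).all()

    def test_reversal_swaps_directions(self):
        """Reversing the input sequence reverses time and swaps the
        forward/backward halves of the output."""
        rng = np.random.default_rng(2)
        lstm = BiLSTM(4, 6, rng)
        # share parameters across directions to make the symmetry exact
        lstm.bwd.W.data = lstm.fwd.W.data.copy()
        lstm.bwd.U.data = lstm.fwd.U.data.copy()
        lstm.bwd.b.data = lstm.fwd.b.data.copy()
        x = rng.normal(size=(1, 3, 4))
        mask = np.ones((1, 3))
        y = lstm(Tensor(x), mask).data
        y_rev = lstm(Tensor(x[:, ::-1].copy()), mask).data
        hd = 3
        assert np.allclose(y[:, :, :hd], y_rev[:, ::-1, hd:], atol=1e-12)
        assert np.allclose(y[:, :, hd:], y_rev[:, ::-1, :hd], atol=1e-12)

    def test_outputs_bounded_by_tanh_range(self):
        rng = np.random.default_rng(3)
        lstm = BiLSTM(4, 6, rng)
        x = Tensor(np.zeros((1, 4, 4)))
        y = lstm(x, np.ones((1, 4)))
        assert (np.abs(y.data) < 1.0).all()
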