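"""Channel attention gate, token embedding, encoder layer, distilling
stack and predictor head: contracts and reductions to simple cases."""

import math

import numpy as np
import pytest

from cst.autodiff import Tensor
from cst.exceptions import ParameterError
from cst.layers import (AttentionBlock, ChannelAttentionParams,
                        DistillLayerParams, PredictHeadParams,
                        TokenEmbedParams, _sinusoid_position_codes,
                        channel_attention, dense_attention, distill_forward,
                        distill_output_length, multi_head, predict_head,
                        token_embed)


def _ca_params(C, hidden, w0=None, w1=None):
    rng = np.random.default_rng(0)
    p = ChannelAttentionParams.init(rng, C, max(1, C // hidden))
    if w0 is not None:
        p.W0.data = np.asarray(w0, dtype=np.float32)
    if w1 is not None:
        p.W1.data = np.asarray(w1, dtype=np.float32)
    return p


class TestChannelAttention:
    def test_zero_weights_give_half_gate(self):
        C = 4
        p = ChannelAttentionParams.init(np.random.default_rng(0), C, 2)
        p.W0.data[:] = 0
        p.W1.data[:] = 0
        X = np.random.default_rng(1).standard_normal((16, C))
        np.testing.assert_allclose(channel_attention(X, p), 0.5 * X,
                                   rtol=1e-6)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            C = int(rng.integers(1, 12))
            p = ChannelAttentionParams.init(rng, C, 2)
            X = 10 * rng.standard_normal((32, C))
            out = channel_attention(X, p)
            with np.errstate(divide="ignore", invalid="ignore"):
                gates = out / X
            gates = gates[np.isfinite(gates)]
            assert np.all(gates > 0) and np.all(gates < 1)

    def test_constant_in_time_input_doubles_statistic(self):
        """Constant signal per channel: avg-pool == max-pool, so the gate
        is sigmoid(2 * W1 W0 x)."""
        rng = np.random.default_rng(3)
        C = 3
        p = ChannelAttentionParams.init(rng, C, 2)
        x = rng.standard_normal(C).astype(np.float32)
        X = np.tile(x, (8, 1))
        out = channel_attention(X, p)
        z = p.W1.data @ (p.W0.data @ x)
        gate = 1 / (1 + np.exp(-2 * z))
        np.testing.assert_allclose(out, X * gate, rtol=1e-5)

    def test_channel_mismatch_rejected(self):
        p = ChannelAttentionParams.init(np.random.default_rng(0), 4, 2)
        with pytest.raises(ParameterError):
            channel_attention(np.zeros((8, 5)), p)


class TestTokenEmbed:
    def test_output_width_is_d_model(self):
        p = TokenEmbedParams.init(np.random.default_rng(0), C=19, d_model=128)
        out = token_embed(np.random.default_rng(1).standard_normal((64, 19)), p)
        assert out.shape == (64, 128)

    def test_zero_weights_no_position_gives_zeros(self):
        p = TokenEmbedParams.init(np.random.default_rng(0), C=3, d_model=8,
                                  use_position=False)
        p.weight.data[:] = 0
        p.bias.data[:] = 0
        out = token_embed(np.random.default_rng(1).standard_normal((32, 3)), p)
        np.testing.assert_array_equal(out, np.zeros((32, 8)))

    def test_position_codes_distinct_up_to_1e4(self):
        pe = _sinusoid_position_codes(10_000, 64)
        # successive codes differ, and a random sample of pairs differ
        assert np.min(np.linalg.norm(np.diff(pe, axis=0), axis=1)) > 1e-4
        rng = np.random.default_rng(0)
        i = rng.integers(0, 10_000, 500)
        j = rng.integers(0, 10_000, 500)
        mask = i != j
        d = np.linalg.norm(pe[i[mask]] - pe[j[mask]], axis=1)
        assert np.all(d > 1e-6)


class TestMultiHead:
    def test_single_head_identity_projections_match_manual_composition(self):
        """With identity Q/K/V/output maps the layer must equal the
        independently composed residual + layernorm + FFN chain around the
        dense-attention oracle."""
        rng = np.random.default_rng(4)
        d = 6
        block = AttentionBlock.init(rng, d_model=d, d_ff=12, n_heads=1)
        eye = np.eye(d, dtype=np.float32)
        for W in (block.Wq, block.Wk, block.Wv, block.Wo):
            W.data = eye.copy()
        for b in (block.bq, block.bk, block.bv, block.bo):
            b.data[:] = 0
        X = rng.standard_normal((5, d)).astype(np.float32)

        def ln(v, g, b):
            mu = v.mean(axis=-1, keepdims=True)
            sd = np.sqrt(((v - mu) ** 2).mean(axis=-1, keepdims=True) + 1e-5)
            return (v - mu) / sd * g + b

        h1 = ln(X + dense_attention(X, X, X), block.ln1_g.data,
                block.ln1_b.data)
        ffn = np.maximum(h1 @ block.W1.data + block.b1.data, 0) \
            @ block.W2.data + block.b2.data
        expected = ln(h1 + ffn, block.ln2_g.data, block.ln2_b.data)
        np.testing.assert_allclose(multi_head(X, block, sparse=False),
                                   expected, atol=1e-5)

    def test_output_shape_matches_d_model_128(self):
        rng = np.random.default_rng(5)
        block = AttentionBlock.init(rng, d_model=128, d_ff=512, n_heads=8)
        for L in (1, 7, 33):
            out = multi_head(rng.standard_normal((L, 128)), block, sparse=True)
            assert out.shape == (L, 128)

    def test_repeat_call_bitwise_identical(self):
        rng = np.random.default_rng(6)
        block = AttentionBlock.init(rng, d_model=16, d_ff=32, n_heads=4)
        X = rng.standard_normal((12, 16))
        a = multi_head(X, block, sparse=True)
        b = multi_head(X, block, sparse=True)
        np.testing.assert_array_equal(a, b)

    def test_sparse_and_dense_agree_when_all_queries_active(self):
        # a large query factor saturates u at L, so sparsity degenerates
        rng = np.random.default_rng(7)
        block = AttentionBlock.init(rng, d_model=8, d_ff=16, n_heads=2)
        X = rng.standard_normal((6, 8))
        np.testing.assert_allclose(multi_head(X, block, sparse=True, c=10.0),
                                   multi_head(X, block, sparse=False),
                                   atol=1e-6)


class TestDistill:
    def test_default_geometry_halves_even_lengths(self):
        assert distill_output_length(2048) == 1024
        assert distill_output_length(64) == 32
        # odd lengths round up: ceil(L/2)
        assert distill_output_length(5) == 3

    def test_forward_length_2048_to_1024(self):
        rng = np.random.default_rng(8)
        p = DistillLayerParams.init(rng, d_model=4)
        out = distill_forward(rng.standard_normal((2048, 4)), p)
        assert out.shape == (1024, 4)

    def test_five_stacked_layers_reach_64(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((2048, 4))
        lengths = []
        for _ in range(5):
            p = DistillLayerParams.init(rng, d_model=4)
            x = distill_forward(x, p)
            lengths.append(x.shape[0])
        assert lengths == [1024, 512, 256, 128, 64]

    def test_identity_conv_on_nonnegative_input_is_pure_maxpool(self):
        """An identity convolution kernel and x >= 0 make ELU transparent,
        so the layer reduces to max pooling."""
        d = 3
        p = DistillLayerParams.init(np.random.default_rng(10), d_model=d)
        p.weight.data[:] = 0
        p.bias.data[:] = 0
        # centre tap of the kernel = identity map
        p.weight.data[d:2 * d] = np.eye(d, dtype=np.float32)
        x = np.abs(np.random.default_rng(11).standard_normal((16, d)))
        out = distill_forward(x, p)
        padded = np.full((18, d), -np.inf)
        padded[1:17] = x
        expected = np.stack([padded[2 * i:2 * i + 3].max(axis=0)
                             for i in range(8)])
        np.testing.assert_allclose(out, expected, rtol=1e-6)


class TestPredictHead:
    def test_zero_weights_uniform_probabilities(self):
        p = PredictHeadParams.init(np.random.default_rng(12), 8, 3)
        p.W.data[:] = 0
        p.b.data[:] = 0
        logits = predict_head(np.random.default_rng(13).standard_normal((6, 8)), p)
        np.testing.assert_array_equal(logits, np.zeros(3))

    def test_single_position_pooling_is_identity(self):
        rng = np.random.default_rng(14)
        p = PredictHeadParams.init(rng, 4, 2)
        h = rng.standard_normal((1, 4)).astype(np.float32)
        expected = h[0] @ p.W.data + p.b.data
        np.testing.assert_allclose(predict_head(h, p), expected, atol=1e-6)

    def test_logits_finite_for_large_inputs(self):
        rng = np.random.default_rng(15)
        p = PredictHeadParams.init(rng, 4, 2)
        h = np.full((32, 4), 1e6)
        assert np.all(np.isfinite(predict_head(h, p)))
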