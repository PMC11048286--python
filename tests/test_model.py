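"""Configuration validation, encoder assembly, full forward pass and
checkpoint round trips."""

import numpy as np
import pytest

from cst.exceptions import ConfigurationError, DataError
from cst.layers import pair_counter, select_active_queries
from cst.model import (ConvSparseTransformer, EncoderStack, ModelConfig,
                       TrainConfig, load_checkpoint, model_forward,
                       save_checkpoint)


class TestModelConfig:
    def test_defaults_are_full_scale_architecture(self):
        cfg = ModelConfig(in_channels=19, n_classes=2)
        assert (cfg.n_sparse_layers, cfg.n_full_layers) == (3, 3)
        assert (cfg.n_conv_layers, cfg.n_pool_layers) == (5, 5)
        assert (cfg.n_heads, cfg.d_model, cfg.d_ff) == (8, 128, 512)

    @pytest.mark.parametrize("kw", [
        dict(d_model=100, n_heads=8),          # not divisible
        dict(n_conv_layers=4, n_pool_layers=5),
        dict(query_factor=0.0),
        dict(n_classes=1),
    ])
    def test_invalid_configs_rejected(self, kw):
        base = dict(in_channels=4, n_classes=2)
        base.update(kw)
        with pytest.raises(ConfigurationError):
            ModelConfig(**base)

    def test_layer_plan_interleaving(self):
        plan = ModelConfig(in_channels=4, n_classes=2).layer_plan()
        kinds = [k for k, _ in plan]
        distills = [d for _, d in plan]
        assert kinds == ["sparse"] * 3 + ["full"] * 3
        assert distills == [True] * 5 + [False]

    def test_ablated_plans(self):
        cfg = ModelConfig(in_channels=4, n_classes=2,
                          use_sparse_attention=False)
        assert all(k == "full" for k, _ in cfg.layer_plan())
        cfg = ModelConfig(in_channels=4, n_classes=2, use_distillation=False)
        assert not any(d for _, d in cfg.layer_plan())

    def test_default_reduction_handles_few_channels(self):
        assert ModelConfig(in_channels=4, n_classes=2).reduction == 2
        assert ModelConfig(in_channels=1, n_classes=2).reduction == 1
        assert ModelConfig(in_channels=19, n_classes=2,
                           channel_reduction=16).reduction == 16

    def test_from_tuple_default_is_reference_config(self):
        cfg = ModelConfig.from_tuple([3, 3, 5, 5, 512, 128, 8],
                                     in_channels=19, n_classes=2)
        assert cfg == ModelConfig(in_channels=19, n_classes=2)

    def test_train_presets(self):
        mdd = TrainConfig.preset("mdd")
        assert (mdd.epochs, mdd.batch_size, mdd.learning_rate) == (50, 64, 1e-3)
        ph = TrainConfig.preset("pharmaco")
        assert (ph.epochs, ph.batch_size, ph.learning_rate) == (300, 32, 1e-4)


class TestEncoderStack:
    def test_parameter_count_deterministic_and_frozen(self):
        cfg = ModelConfig(in_channels=19, n_classes=2, seed=0)
        a = EncoderStack.from_config(cfg)
        b = EncoderStack.from_config(cfg)
        assert a.n_parameters == b.n_parameters == 1_443_790
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_no_distill_stack_has_no_conv_parameters(self):
        cfg = ModelConfig(in_channels=4, n_classes=2, use_distillation=False)
        stack = EncoderStack.from_config(cfg)
        assert all(d is None for d in stack.distills)


class TestModelForward:
    def test_full_config_logit_shape(self):
        cfg = ModelConfig(in_channels=19, n_classes=2, seed=1)
        stack = EncoderStack.from_config(cfg)
        X = np.random.default_rng(0).standard_normal((2, 2048, 19))
        out = model_forward(X, stack)
        assert out.data.shape == (2, 2)
        assert np.all(np.isfinite(out.data))

    def test_all_ablations_off_is_plain_dense_transformer(self):
        cfg = ModelConfig(in_channels=3, n_classes=2,
                          n_sparse_layers=1, n_full_layers=1,
                          n_conv_layers=2, n_pool_layers=2,
                          d_model=16, d_ff=32, n_heads=2,
                          use_channel_attention=False,
                          use_sparse_attention=False,
                          use_distillation=False)
        stack = EncoderStack.from_config(cfg)
        assert stack.channel_attn is None
        pair_counter.reset()
        X = np.random.default_rng(1).standard_normal((1, 32, 3))
        model_forward(X, stack)
        # every attention layer ran dense over the full length
        assert pair_counter.layers == [("dense", 32 * 32)] * 2

    def test_sparse_layer_pair_counts_in_forward(self):
        cfg = ModelConfig(in_channels=3, n_classes=2,
                          n_sparse_layers=2, n_full_layers=1,
                          n_conv_layers=2, n_pool_layers=2,
                          d_model=16, d_ff=32, n_heads=2, dropout=0.0)
        stack = EncoderStack.from_config(cfg)
        pair_counter.reset()
        model_forward(np.zeros((1, 64, 3)), stack)
        u64 = len(select_active_queries(64))
        u32 = len(select_active_queries(32))
        assert pair_counter.layers == [("sparse", u64 * 64),
                                       ("sparse", u32 * 32),
                                       ("dense", 16 * 16)]

    def test_duplicated_inputs_give_identical_logits(self):
        cfg = ModelConfig(in_channels=2, n_classes=3, n_sparse_layers=1,
                          n_full_layers=1, n_conv_layers=1, n_pool_layers=1,
                          d_model=8, d_ff=16, n_heads=2)
        stack = EncoderStack.from_config(cfg)
        x = np.random.default_rng(2).standard_normal((1, 16, 2))
        batch = np.concatenate([x, x])
        out = model_forward(batch, stack).data
        np.testing.assert_array_equal(out[0], out[1])

    def test_too_short_input_names_minimum_length(self):
        cfg = ModelConfig(in_channels=2, n_classes=2)
        stack = EncoderStack.from_config(cfg)
        with pytest.raises(ConfigurationError, match="32"):
            model_forward(np.zeros((1, 16, 2)), stack)

    def test_channel_mismatch_rejected(self):
        cfg = ModelConfig(in_channels=4, n_classes=2)
        stack = EncoderStack.from_config(cfg)
        with pytest.raises(DataError):
            model_forward(np.zeros((1, 64, 3)), stack)


class TestCheckpoint:
    def test_roundtrip_reproduces_config_and_logits(self, tmp_path,
                                                    tiny_task, tiny_model_cfg):
        model = ConvSparseTransformer(tiny_task, tiny_model_cfg)
        res = model.fit(TrainConfig(epochs=1, batch_size=16, seed=0))
        path = save_checkpoint(res.stack, tmp_path / "ckpt.npz")
        back = load_checkpoint(path)
        assert back.config == tiny_model_cfg
        X = tiny_task.epochs[:4]
        np.testing.assert_array_equal(model_forward(X, res.stack).data,
                                      model_forward(X, back).data)
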