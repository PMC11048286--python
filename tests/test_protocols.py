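"""Training loop contracts, holdout/CV protocols, the ablation
switchboard and the sensitivity sweep."""

import numpy as np
import pytest

from cst.exceptions import ParameterError
from cst.model import ConvSparseTransformer, ModelConfig, TrainConfig
from cst.protocols import (ABLATION_GRID, run_ablation, run_cv,
                           run_holdout_repeats, run_sensitivity)


class TestTraining:
    def test_loss_history_length_and_finiteness(self, tiny_task,
                                                tiny_model_cfg):
        res = ConvSparseTransformer(tiny_task, tiny_model_cfg).fit(
            TrainConfig(epochs=1, batch_size=8, seed=0))
        assert len(res.loss_history) == 1
        assert np.isfinite(res.loss_history[0])

    def test_zero_learning_rate_leaves_parameters_unchanged(
            self, tiny_task, tiny_model_cfg):
        from cst.model import EncoderStack
        init = EncoderStack.from_config(tiny_model_cfg)
        res = ConvSparseTransformer(tiny_task, tiny_model_cfg).fit(
            TrainConfig(epochs=1, batch_size=8, learning_rate=0.0, seed=0))
        for p0, p1 in zip(init.parameters(), res.stack.parameters()):
            np.testing.assert_array_equal(p0.data, p1.data)

    def test_loss_decreases_on_easy_task(self, tiny_task, tiny_model_cfg,
                                         tiny_train_cfg):
        res = ConvSparseTransformer(tiny_task, tiny_model_cfg).fit(
            tiny_train_cfg)
        assert res.loss_history[-1] < res.loss_history[0]

    def test_fit_is_reproducible(self, tiny_task, tiny_model_cfg):
        tc = TrainConfig(epochs=2, batch_size=8, seed=3)
        a = ConvSparseTransformer(tiny_task, tiny_model_cfg).fit(tc)
        b = ConvSparseTransformer(tiny_task, tiny_model_cfg).fit(tc)
        assert a.loss_history == b.loss_history
        for pa, pb in zip(a.stack.parameters(), b.stack.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_summary_mentions_architecture(self, tiny_task, tiny_model_cfg):
        res = ConvSparseTransformer(tiny_task, tiny_model_cfg).fit(
            TrainConfig(epochs=0, batch_size=8))
        text = res.summary()
        assert "sparse" in text and "d_model" in text


class TestHoldoutRepeats:
    def test_two_repeats_aggregate(self, tiny_task, tiny_model_cfg):
        result = run_holdout_repeats(
            tiny_task, tiny_model_cfg,
            TrainConfig(epochs=1, batch_size=16, seed=0),
            n_repeats=2, seed=1)
        assert len(result.folds) == 2
        mu, sd = result.aggregate()["accuracy"]
        assert 0.0 <= mu <= 1.0 and sd >= 0.0

    def test_fixed_seed_reproduces_aggregate(self, tiny_task, tiny_model_cfg):
        tc = TrainConfig(epochs=1, batch_size=16, seed=0)
        a = run_holdout_repeats(tiny_task, tiny_model_cfg, tc, 2, seed=5)
        b = run_holdout_repeats(tiny_task, tiny_model_cfg, tc, 2, seed=5)
        assert a.aggregate() == b.aggregate()

    def test_untrained_model_near_chance_on_balanced_data(
            self, tiny_task, tiny_model_cfg):
        """Zero training epochs = random init: accuracy inside binomial
        bounds around 0.5 over 10 repeats."""
        result = run_holdout_repeats(
            tiny_task, tiny_model_cfg,
            TrainConfig(epochs=0, batch_size=16, seed=0),
            n_repeats=10, seed=2)
        assert 0.3 <= result.mean("accuracy") <= 0.7


class TestCrossValidation:
    def test_folds_cover_every_epoch_once(self, tiny_task, tiny_model_cfg):
        result = run_cv(tiny_task, 4, tiny_model_cfg,
                        TrainConfig(epochs=0, batch_size=16), seed=0)
        total = sum(r.n for r in result.folds)
        assert total == len(tiny_task)

    def test_seed_determinism(self, tiny_task, tiny_model_cfg):
        tc = TrainConfig(epochs=1, batch_size=16, seed=0)
        a = run_cv(tiny_task, 3, tiny_model_cfg, tc, seed=4)
        b = run_cv(tiny_task, 3, tiny_model_cfg, tc, seed=4)
        assert a.aggregate() == b.aggregate()

    def test_learns_easy_task(self, tiny_task, tiny_model_cfg,
                              tiny_train_cfg):
        result = run_cv(tiny_task, 3, tiny_model_cfg, tiny_train_cfg, seed=0)
        assert result.mean("accuracy") >= 0.9

    def test_to_frame_shape(self, tiny_task, tiny_model_cfg):
        result = run_cv(tiny_task, 3, tiny_model_cfg,
                        TrainConfig(epochs=0, batch_size=16), seed=0)
        df = result.to_frame()
        assert df.shape[0] == 3 and "accuracy" in df.columns


class TestAblation:
    def test_four_rows_with_standard_flag_pattern(self, tiny_task,
                                                   tiny_model_cfg):
        table = run_ablation(tiny_task, tiny_model_cfg,
                             TrainConfig(epochs=0, batch_size=16), seed=0)
        flags = list(zip(table["channel_attention"], table["sparse_attention"],
                         table["distillation"]))
        assert flags == list(ABLATION_GRID)

    def test_no_distill_variant_has_zero_conv_parameters(self):
        from cst.model import EncoderStack
        cfg = ModelConfig(in_channels=3, n_classes=2, n_sparse_layers=1,
                          n_full_layers=1, n_conv_layers=2, n_pool_layers=2,
                          d_model=8, d_ff=16, n_heads=2,
                          use_distillation=False)
        stack = EncoderStack.from_config(cfg)
        assert all(d is None for d in stack.distills)
        full = EncoderStack.from_config(
            ModelConfig(in_channels=3, n_classes=2, n_sparse_layers=1,
                        n_full_layers=1, n_conv_layers=2, n_pool_layers=2,
                        d_model=8, d_ff=16, n_heads=2))
        assert stack.n_parameters < full.n_parameters


class TestSensitivity:
    def test_grid_of_two_tuples_gives_two_rows(self, tiny_task):
        tc = TrainConfig(epochs=0, batch_size=16)
        table = run_sensitivity(
            tiny_task,
            [[1, 1, 2, 2, 32, 16, 2], [2, 1, 2, 2, 32, 16, 2]],
            tc, seed=0, k=2)
        assert len(table) == 2
        assert (table["status"] == "ok").all()

    def test_too_many_pool_layers_yields_error_row(self, tiny_task):
        # T = 64: seven halvings need T >= 128
        table = run_sensitivity(tiny_task, [[1, 1, 7, 7, 32, 16, 2]],
                                TrainConfig(epochs=0, batch_size=16),
                                seed=0, k=2)
        assert len(table) == 1
        assert table.loc[0, "status"].startswith("configuration error")

    def test_inconsistent_tuple_yields_error_row(self, tiny_task):
        table = run_sensitivity(tiny_task, [[1, 1, 2, 3, 32, 16, 2]],
                                TrainConfig(epochs=0, batch_size=16),
                                seed=0, k=2)
        assert table.loc[0, "status"].startswith("configuration error")
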