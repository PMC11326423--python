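"""Architectures, training loop, ridge nested CV, saliency, checkpoints."""

import numpy as np
import pytest

from ihirate import nn
from ihirate.models import (
    DEFAULT_RIDGE_ALPHAS,
    ArchitectureSpec,
    TrainConfig,
    build_conv5fc3,
    build_model,
    build_resnet3d,
    build_secnn,
    load_checkpoint,
    predict_criterion,
    ridge_nested_cv,
    saliency_group_map,
    save_checkpoint,
    top_k_support,
    train_regressor,
)

GRID = (12, 10, 8)
TINY = ArchitectureSpec(family="conv5fc3", channels=(2, 2, 4, 4, 4), fc_widths=(8, 4))


def tiny_spec(family):
    return ArchitectureSpec(
        family=family, channels=(2, 2, 4, 4, 4), fc_widths=(8, 4), se_reduction=2
    )


class TestBuilders:
    def test_conv5fc3_pooled_extents_on_reference_roi(self):
        model = build_conv5fc3((72, 53, 33), TINY, seed=0)
        assert nn.pooled_extents(model.input_extents, 5) == (2, 1, 1)

    def test_forward_shape_contract(self):
        model = build_conv5fc3(GRID, TINY, seed=0)
        out = model.forward(np.random.default_rng(0).random((16,) + GRID))
        assert out.shape == (16,)

    def test_identical_seed_identical_weights(self):
        a = build_conv5fc3(GRID, TINY, seed=5)
        b = build_conv5fc3(GRID, TINY, seed=5)
        for la, lb in zip(a.net.walk(), b.net.walk()):
            for name in la.params:
                np.testing.assert_array_equal(la.params[name], lb.params[name])

    def test_structure_counts(self):
        model = build_conv5fc3(GRID, TINY, seed=0)
        convs = [l for l in model.net.walk() if isinstance(l, nn.Conv3d)]
        linears = [l for l in model.net.walk() if isinstance(l, nn.Linear)]
        assert len(convs) == 5 and len(linears) == 3

    def test_residual_families_have_five_blocks(self):
        for build in (build_resnet3d, build_secnn):
            model = build(GRID, tiny_spec("resnet3d" if build is build_resnet3d else "secnn"), seed=0)
            blocks = [
                l for l in model.net.children() if isinstance(l, nn.ResidualBlock3d)
            ]
            assert len(blocks) == 5

    def test_wrong_family_spec_rejected(self):
        with pytest.raises(ValueError, match="family"):
            build_model("secnn", GRID, TINY, seed=0)

    def test_bad_extents_rejected(self):
        with pytest.raises(ValueError):
            build_conv5fc3((0, 4, 4), TINY, seed=0)


class TestResidualBlocks:
    def test_zeroed_conv_path_passes_shortcut(self):
        rng = np.random.default_rng(0)
        block = nn.ResidualBlock3d(3, 3, rng)
        for layer in block.main.walk():
            for name in layer.params:
                layer.params[name] = np.zeros_like(layer.params[name])
        x = np.abs(rng.normal(size=(2, 3, 4, 4, 4)))  # positive: out ReLU is identity
        np.testing.assert_allclose(block.forward(x), x)

    def test_se_gate_identity_when_forced_to_one(self):
        rng = np.random.default_rng(1)
        se_block = nn.ResidualBlock3d(2, 4, rng, se_reduction=2)
        plain = nn.ResidualBlock3d(2, 4, np.random.default_rng(1))
        # copy the main/shortcut weights so the only difference is the gate
        for src, dst in zip(plain.main.walk(), se_block.main.walk()):
            for name in src.params:
                dst.params[name] = src.params[name].copy()
        for src, dst in zip(plain.shortcut.walk(), se_block.shortcut.walk()):
            for name in src.params:
                dst.params[name] = src.params[name].copy()
        # saturate the gate: huge positive bias on the second FC
        se_block.se.fc2.params["bias"][:] = 50.0
        se_block.se.fc2.params["weight"][:] = 0.0
        x = np.random.default_rng(2).normal(size=(2, 2, 4, 4, 4))
        np.testing.assert_allclose(se_block.forward(x), plain.forward(x), atol=1e-9)

    def test_gate_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        gate = nn.SEGate(4, reduction=2, rng=rng)
        gate.forward(rng.normal(size=(3, 4, 2, 2, 2)))
        assert np.all(gate.gate > 0) and np.all(gate.gate < 1)

    def test_constant_channel_squeeze_is_that_constant(self):
        pool = nn.GlobalAvgPool()
        x = np.full((1, 2, 3, 3, 3), 0.0)
        x[0, 1] = 0.7
        np.testing.assert_allclose(pool.forward(x)[0], [0.0, 0.7])

    def test_se_reduction_exceeding_channels_rejected(self):
        with pytest.raises(ValueError, match="reduction"):
            nn.SEGate(2, reduction=4, rng=np.random.default_rng(0))

    def test_eval_mode_deterministic_despite_dropout(self):
        model = build_resnet3d(GRID, tiny_spec("resnet3d"), seed=0)
        x = np.random.default_rng(4).random((3,) + GRID)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))


def linear_signal_data(n, grid, seed=0, noise=0.0):
    """Labels proportional to one voxel's intensity — trivially learnable."""
    rng = np.random.default_rng(seed)
    x = rng.random((n,) + grid)
    y = 2.0 * x[:, grid[0] // 2, grid[1] // 2, grid[2] // 2]
    if noise:
        y = y + rng.normal(0, noise, n)
    return x, y


class TestTraining:
    def test_learns_linear_signal(self):
        x, y = linear_signal_data(96, GRID, seed=1)
        model = build_conv5fc3(GRID, TINY, seed=0)
        cfg = TrainConfig(max_epochs=5, learning_rate=1e-3, seed=0)
        trained = train_regressor(model, (x[:80], y[:80]), (x[80:], y[80:]), cfg)
        assert trained.train_losses[-1] < trained.train_losses[0]

    def test_best_epoch_attains_minimum(self):
        x, y = linear_signal_data(60, GRID, seed=2, noise=0.3)
        model = build_conv5fc3(GRID, TINY, seed=1)
        cfg = TrainConfig(max_epochs=6, learning_rate=1e-3, seed=1)
        trained = train_regressor(model, (x[:48], y[:48]), (x[48:], y[48:]), cfg)
        assert trained.best_val_loss == min(trained.val_losses)
        assert trained.val_losses[trained.best_epoch - 1] == trained.best_val_loss

    def test_reproducible_given_seed(self):
        x, y = linear_signal_data(48, GRID, seed=3)
        results = []
        for _ in range(2):
            model = build_conv5fc3(GRID, TINY, seed=2)
            cfg = TrainConfig(max_epochs=3, learning_rate=1e-3, seed=2)
            trained = train_regressor(model, (x[:40], y[:40]), (x[40:], y[40:]), cfg)
            results.append(trained.best_val_loss)
        assert results[0] == results[1]

    def test_empty_sets_rejected(self):
        x, y = linear_signal_data(10, GRID)
        model = build_conv5fc3(GRID, TINY, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            train_regressor(model, (x[:0], y[:0]), (x, y), TrainConfig())

    def test_non_finite_loss_aborts_with_diagnostic(self):
        x, y = linear_signal_data(32, GRID, seed=4)
        y = y.copy()
        y[3] = np.nan  # poisoned label surfaces as a non-finite batch loss
        model = build_conv5fc3(GRID, TINY, seed=3)
        cfg = TrainConfig(max_epochs=2, learning_rate=1e-3, seed=3)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_regressor(model, (x[:24], y[:24]), (x[24:], y[24:]), cfg)

    def test_prediction_contracts(self):
        x, y = linear_signal_data(40, GRID, seed=5)
        model = build_conv5fc3(GRID, TINY, seed=4)
        cfg = TrainConfig(max_epochs=2, learning_rate=1e-3, seed=4)
        trained = train_regressor(model, (x[:32], y[:32]), (x[32:], y[32:]), cfg)
        preds = predict_criterion(trained, x[:7])
        assert preds.shape == (7,) and np.all(np.isfinite(preds))
        # duplicated crop -> duplicated prediction
        dup = predict_criterion(trained, np.stack([x[0], x[0]]))
        assert dup[0] == dup[1]
        with pytest.raises(ValueError, match="shape"):
            trained.model.forward(np.zeros((2, 5, 5, 5)))


class TestRidgeNestedCV:
    def test_recovers_linear_voxel_signal(self):
        rng = np.random.default_rng(6)
        x = rng.random((90, 50))
        y = 3.0 * x[:, 7]
        result = ridge_nested_cv(x, y)
        assert np.abs(result.outer_predictions - y).max() < 1e-2

    def test_chosen_alpha_in_grid(self):
        rng = np.random.default_rng(7)
        x = rng.random((60, 30))
        y = x[:, 3] + rng.normal(0, 0.2, 60)
        result = ridge_nested_cv(x, y)
        assert result.alpha in DEFAULT_RIDGE_ALPHAS
        assert all(a in DEFAULT_RIDGE_ALPHAS for a in result.outer_alphas)

    def test_permuted_labels_negative_control(self):
        from ihirate.evaluation import icc

        rng = np.random.default_rng(8)
        x = rng.random((200, 40))
        y = rng.permutation(x[:, 0] * 2.0)
        result = ridge_nested_cv(x, y)
        assert abs(icc(y, result.outer_predictions)) < 0.2

    def test_constant_labels_rejected(self):
        x = np.random.default_rng(9).random((30, 10))
        with pytest.raises(ValueError, match="constant"):
            ridge_nested_cv(x, np.ones(30))


class TestSaliency:
    def test_top_k_exact_count_and_tie_order(self):
        values = np.zeros((4, 4))
        values[0, :2] = 5.0
        values[1, :3] = 5.0  # ties beyond k broken by flat index order
        support = top_k_support(values, 3)
        assert support.sum() == 3
        assert support[0, 0] and support[0, 1] and support[1, 0]

    def test_cnn_saliency_retains_exact_count(self):
        x, y = linear_signal_data(24, GRID, seed=10)
        model = build_conv5fc3(GRID, TINY, seed=5)
        cfg = TrainConfig(max_epochs=2, learning_rate=1e-3, seed=5)
        trained = train_regressor(model, (x[:16], y[:16]), (x[16:], y[16:]), cfg)
        grad, support = saliency_group_map(trained, x[:4], n_keep=50)
        assert support.sum() == 50
        assert grad.shape == GRID

    def test_ridge_saliency_is_abs_coefficients(self):
        rng = np.random.default_rng(11)
        grid = (5, 4, 3)
        x = rng.random((40, np.prod(grid)))
        y = x @ rng.normal(0, 1, x.shape[1])
        result = ridge_nested_cv(x, y, input_extents=grid)
        grad, support = saliency_group_map(result, n_keep=10)
        from ihirate.preprocess import unflatten

        np.testing.assert_allclose(grad, np.abs(unflatten(result.model.coef_, grid)))
        assert support.sum() == 10


class TestCheckpoints:
    def test_round_trip_reproduces_predictions(self, tmp_path):
        x, y = linear_signal_data(40, GRID, seed=12)
        model = build_conv5fc3(GRID, TINY, seed=6)
        cfg = TrainConfig(max_epochs=3, learning_rate=1e-3, seed=6)
        trained = train_regressor(
            model, (x[:32], y[:32]), (x[32:], y[32:]), cfg,
            criterion="C2", hemisphere="right", strategy="demo",
        )
        path = tmp_path / "model.npz"
        save_checkpoint(trained, path)
        loaded = load_checkpoint(path)
        assert loaded.criterion == "C2" and loaded.strategy == "demo"
        assert loaded.best_val_loss == trained.best_val_loss
        np.testing.assert_allclose(
            predict_criterion(loaded, x[:5]), predict_criterion(trained, x[:5])
        )

    def test_reloaded_model_reproduces_validation_loss(self, tmp_path):
        x, y = linear_signal_data(40, GRID, seed=13)
        model = build_conv5fc3(GRID, TINY, seed=7)
        cfg = TrainConfig(max_epochs=3, learning_rate=1e-3, seed=7)
        trained = train_regressor(model, (x[:32], y[:32]), (x[32:], y[32:]), cfg)
        path = tmp_path / "m.npz"
        save_checkpoint(trained, path)
        loaded = load_checkpoint(path)
        val_pred = predict_criterion(loaded, x[32:])
        assert float(np.mean((val_pred - y[32:]) ** 2)) == pytest.approx(
            trained.best_val_loss, rel=1e-10
        )
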