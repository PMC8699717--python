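"""Classifier: architecture contract, staged training, determinism."""

import numpy as np
import pytest

from atacre import nn
from atacre.classifier import (
    CisREClassifier,
    ModelConfig,
    TUNING_GRID,
    build_model,
    predict,
    small_config,
    train_staged,
)


def toy_dataset(n=96, seed=0, window=60):
    """Linearly separable 4-class toy data in both input branches."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, size=n)
    X = rng.normal(0, 0.3, size=(n, 10, window))
    F = rng.normal(0, 0.3, size=(n, 19))
    for i, cls in enumerate(y):
        X[i, 4 + cls, :] += 2.0      # class-specific signal row
        F[i, cls] += 2.0             # class-specific feature
    splits = np.where(np.arange(n) % 4 == 0, "validation", "train")
    return X, F, y, splits


def toy_config(**kw):
    defaults = dict(
        window_len=60, conv_kernel=9, conv_blocks=2, filters_per_block=(8, 8),
        branch_dense=16, joint_dense=16, branch_epochs=3, joint_epochs=3,
        early_stopping_patience=2, seed=11, learning_rate=0.01,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestModelConfig:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(conv_kernel=10)

    def test_filters_must_match_blocks(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_blocks=3)

    def test_n_classes_fixed(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=5)

    def test_collapsing_window_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            ModelConfig(window_len=64, conv_blocks=4)

    def test_tuning_grid_menu(self):
        assert ModelConfig().conv_kernel in TUNING_GRID["conv_kernel"]
        assert ModelConfig().conv_blocks in TUNING_GRID["conv_blocks"]
        assert ModelConfig().branch_dense in TUNING_GRID["branch_dense"]


class TestArchitecture:
    def test_default_build_matches_tuned_description(self):
        model = build_model(ModelConfig())
        desc = model.describe()
        convs = [d for d in desc if d["type"] == "conv1d"]
        assert len(convs) == 8  # two per block
        assert all(c["kernel"] == 19 and c["stride"] == 1 for c in convs)
        assert [c["filters"] for c in convs] == [256, 256, 256, 256, 512, 512, 512, 512]
        pools = [d for d in desc if d["type"] == "max_pool"]
        assert len(pools) == 4 and all(p["pool"] == 2 for p in pools)
        assert len([d for d in desc if d["type"] == "batch_norm"]) == 8
        dense = [d for d in desc if d["type"] == "dense"]
        assert dense[-1]["units"] == 2048

    def test_forward_pass_outputs_probabilities(self):
        model = build_model(toy_config())
        X = np.zeros((3, 60, 10))
        F = np.zeros((3, 19))
        probs = nn.softmax(model._forward_joint(X, F, training=False))
        assert probs.shape == (3, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestStagedTraining:
    def test_stage_order_and_history(self):
        X, F, y, splits = toy_dataset()
        model = train_staged(X, F, y, splits, toy_config())
        assert list(model.history) == ["deep_branch", "aux_branch", "joint"]
        assert model.trained

    def test_missing_validation_split_rejected(self):
        X, F, y, _ = toy_dataset()
        with pytest.raises(ValueError, match="validation"):
            train_staged(X, F, y, ["train"] * len(y), toy_config())

    def test_label_outside_classes_rejected(self):
        X, F, y, splits = toy_dataset()
        bad = ["promoter"] * (len(y) - 1) + ["super_enhancer"]
        with pytest.raises(ValueError, match="outside"):
            train_staged(X, F, bad, splits, toy_config())

    def test_same_seed_reproduces_validation_loss(self):
        X, F, y, splits = toy_dataset()
        m1 = train_staged(X, F, y, splits, toy_config())
        m2 = train_staged(X, F, y, splits, toy_config())
        assert (
            m1.history["joint"][-1]["val_loss"]
            == m2.history["joint"][-1]["val_loss"]
        )

    def test_training_loss_decreases_over_first_epochs(self):
        X, F, y, splits = toy_dataset(n=160)
        cfg = toy_config(branch_epochs=3, joint_epochs=1)
        model = train_staged(X, F, y, splits, cfg)
        losses = [e["train_loss"] for e in model.history["deep_branch"][:3]]
        assert losses[0] > losses[1] > losses[2]


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self):
        X, F, y, splits = toy_dataset(n=128, seed=3)
        model = train_staged(X, F, y, splits, toy_config(branch_epochs=6, joint_epochs=6))
        from atacre.encoder import EncodingStats
        from atacre.features import FeatureStats

        model.encoding_stats = EncodingStats(np.zeros((5, 60)), np.ones((5, 60)))
        model.feature_stats = FeatureStats(np.zeros(19), np.ones(19))
        return model, X, F, y

    def test_probabilities_sum_to_one(self, trained):
        model, X, F, _ = trained
        probs = predict(model, X, F)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_size_independence(self, trained):
        model, X, F, _ = trained
        a = predict(model, X, F, batch_size=7)
        b = predict(model, X, F, batch_size=128)
        assert np.allclose(a, b, atol=1e-12)

    def test_learns_the_separable_toy_problem(self, trained):
        model, X, F, y = trained
        pred = predict(model, X, F).argmax(axis=1)
        assert (pred == y).mean() > 0.9

    def test_untrained_model_rejected(self):
        model = build_model(toy_config())
        with pytest.raises(ValueError, match="untrained"):
            predict(model, np.zeros((1, 10, 60)), np.zeros((1, 19)))

    def test_missing_stats_rejected(self, trained):
        model, X, F, _ = trained
        bare = build_model(model.config)
        bare.trained = True
        with pytest.raises(ValueError, match="statistics"):
            predict(bare, X, F)

    def test_wrong_shape_rejected(self, trained):
        model, X, F, _ = trained
        with pytest.raises(ValueError, match="encodings"):
            predict(model, np.zeros((2, 10, 61)), np.zeros((2, 19)))

    def test_save_load_roundtrip(self, trained, tmp_path):
        model, X, F, _ = trained
        model.save(str(tmp_path / "model"))
        back = CisREClassifier.load(str(tmp_path / "model"))
        assert np.allclose(
            predict(model, X, F), predict(back, X, F), atol=1e-12
        )


class TestSmallConfig:
    def test_small_config_valid_and_cheap(self):
        cfg = small_config(seed=1)
        assert cfg.conv_blocks < ModelConfig().conv_blocks

        def n_params(config):
            model = build_model(config)
            return sum(p.value.size for p in model._all_params())

        assert n_params(cfg) < n_params(ModelConfig()) / 50
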