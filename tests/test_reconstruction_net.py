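"""Generator architecture, data pipeline, short training runs, inference."""

import numpy as np
import pytest

from densestorm.localization_io import render_histogram
from densestorm.losses import LossConfig
from densestorm.nn import Tensor
from densestorm.reconstruction_net import (
    GeneratorConfig,
    TrainingConfig,
    build_generator,
    layer_shapes,
    load_model,
    make_training_pairs,
    predict,
    rotate_and_center_crop,
    save_model,
    train,
)

TINY = GeneratorConfig.tiny()
FAST_CFG = TrainingConfig(epochs=5, patch_crop=96, patch_train=64, batch_size=4, seed=3)
FAST_LOSS = LossConfig(mssim_levels=2)


@pytest.fixture(scope="module")
def training_pairs(filament_dataset):
    _, locs = filament_dataset
    rng = np.random.default_rng(11)
    return make_training_pairs(locs, "gaussian", FAST_CFG, rng, 10)


@pytest.fixture(scope="module")
def trained_model(training_pairs):
    model = build_generator(TINY, seed=5)
    cfg = TrainingConfig(epochs=12, patch_crop=96, patch_train=64, batch_size=4, seed=5)
    history = train(model, training_pairs[2:], cfg, FAST_LOSS,
                    validation_pairs=training_pairs[:2])
    return model, history


class TestArchitecture:
    def test_full_profile_matches_printed_schedule(self):
        """Eight stride-2 levels, filters 64-128-256-512-...-512, tanh head."""
        records = layer_shapes(GeneratorConfig(), 512)
        enc = [r for r in records if r["name"].startswith("enc")]
        assert [r["out_channels"] for r in enc] == [64, 128, 256, 512, 512, 512, 512, 512]
        assert [r["size"] for r in enc] == [256, 128, 64, 32, 16, 8, 4, 2]
        dec = [r for r in records if r["name"].startswith("dec")]
        assert [r["out_channels"] for r in dec] == [512, 512, 512, 512, 256, 128, 64]
        skips = [r for r in records if r["name"].startswith("skip")]
        assert [r["out_channels"] for r in skips] == [1024, 1024, 1024, 1024, 512, 256, 128]
        assert records[-1] == {"name": "head(tanh)", "out_channels": 1, "size": 512}
        cfg = GeneratorConfig()
        assert cfg.kernel_size == 4 and cfg.stride == 2 and cfg.depth == 8

    def test_output_shape_equals_input_shape(self):
        model = build_generator(TINY, seed=0)
        out = model(Tensor(np.zeros((1, 1, 64, 64))))
        assert out.shape == (1, 1, 64, 64)

    def test_bottleneck_spatial_size(self):
        records = layer_shapes(GeneratorConfig(), 512)
        assert records[7] == {"name": "enc8", "out_channels": 512, "size": 2}

    def test_indivisible_input_rejected(self):
        model = build_generator(TINY, seed=0)
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 1, 60, 60))))
        with pytest.raises(ValueError):
            layer_shapes(GeneratorConfig(), 500)

    def test_same_seed_same_initial_parameters(self):
        m1 = build_generator(TINY, seed=7)
        m2 = build_generator(TINY, seed=7)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_checkpoint_roundtrip(self, tmp_path, trained_model):
        model, _ = trained_model
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        for p1, p2 in zip(model.state_dict(), back.state_dict()):
            np.testing.assert_array_equal(p1, p2)
        x = np.random.default_rng(0).poisson(0.3, (64, 64)).astype(float)
        np.testing.assert_array_equal(
            predict(model, x, tile=64).values, predict(back, x, tile=64).values
        )


class TestTrainingPairs:
    def test_same_seed_identical_stream(self, filament_dataset):
        _, locs = filament_dataset
        p1 = make_training_pairs(locs, "gaussian", FAST_CFG, np.random.default_rng(2), 3)
        p2 = make_training_pairs(locs, "gaussian", FAST_CFG, np.random.default_rng(2), 3)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.input_patch, b.input_patch)
            np.testing.assert_array_equal(a.target_patch, b.target_patch)

    def test_full_fraction_dominates_any_subset(self, filament_dataset):
        # a fraction-1.0 input holds at least the counts of any frame-window
        # subset on the same crop
        from densestorm.localization_io import split_by_frame_window

        _, locs = filament_dataset
        cfg = TrainingConfig(
            epochs=1, patch_crop=64, patch_train=64, batch_size=1, seed=0,
            sparse_fraction_range=(1.0, 1.0), rotate=False,
        )
        from densestorm.reconstruction_net import make_target_field

        full = make_training_pairs(locs, "gaussian", cfg, np.random.default_rng(4), 2)
        full_hist, _ = make_target_field(locs, "gaussian", cfg)
        h, w = full_hist.shape
        extent = (
            full_hist.origin[0], full_hist.origin[0] + w * cfg.pixel_size,
            full_hist.origin[1], full_hist.origin[1] + h * cfg.pixel_size,
        )
        for pair in full:
            r0, c0 = pair.provenance["crop"]
            occupied_full = (pair.input_patch > -1).sum()
            sub, _ = split_by_frame_window(locs, 0.2, np.random.default_rng(1))
            sub_hist = render_histogram(sub, cfg.pixel_size, extent, shape=(h, w))
            sub_crop = sub_hist.counts[r0 : r0 + 64, c0 : c0 + 64]
            assert occupied_full >= (sub_crop > 0).sum()

    def test_right_angle_rotation_is_exact(self, rng):
        patch = rng.random((96, 96))
        rotated = rotate_and_center_crop(patch, 90.0, 64)
        reference = rotate_and_center_crop(np.rot90(patch), 0.0, 64)
        np.testing.assert_allclose(rotated, reference, atol=1e-12)

    def test_registered_geometry(self, training_pairs):
        for pair in training_pairs:
            assert pair.input_patch.shape == pair.target_patch.shape == (64, 64)
            assert pair.input_patch.min() >= -1 and pair.input_patch.max() <= 1


class TestTrain:
    def test_loss_decreases_and_history_complete(self, trained_model):
        _, history = trained_model
        assert len(history) == 12
        for column in ("train_frc", "train_mssim", "train_l1", "train_total",
                       "val_total"):
            assert np.isfinite(history[column]).all()
        assert history.train_total.iloc[-3:].mean() < history.train_total.iloc[0]

    def test_seeded_runs_reproduce_loss_history(self, training_pairs):
        histories = []
        for _ in range(2):
            model = build_generator(TINY, seed=9)
            history = train(model, training_pairs[:4], FAST_CFG, FAST_LOSS)
            histories.append(history)
        np.testing.assert_allclose(
            histories[0].train_total.values, histories[1].train_total.values, rtol=1e-12
        )

    def test_empty_stream_rejected(self):
        model = build_generator(TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, [], FAST_CFG, FAST_LOSS)


class TestPredict:
    def test_deterministic_outputs(self, trained_model, rng):
        model, _ = trained_model
        x = rng.poisson(0.3, (64, 64)).astype(float)
        out1 = predict(model, x, tile=64).values
        out2 = predict(model, x, tile=64).values
        np.testing.assert_array_equal(out1, out2)

    def test_output_nonnegative(self, trained_model, rng):
        model, _ = trained_model
        out = predict(model, rng.poisson(0.3, (64, 64)).astype(float), tile=64)
        assert out.values.min() >= 0

    def test_zero_input_near_constant(self, trained_model):
        model, _ = trained_model
        out = predict(model, np.zeros((64, 64)), tile=64).values
        scale = model.meta["target_scale"]
        assert out.std() < 0.25 * scale

    def test_tiled_prediction_consistent_with_single_pass(self, trained_model, filament_dataset):
        model, _ = trained_model
        _, locs = filament_dataset
        hist = render_histogram(locs, 10.0, (0, 2560, 0, 2560))  # 256 x 256
        single = predict(model, hist, tile=512).values
        tiled = predict(model, hist, tile=128).values
        diff = np.abs(single - tiled)
        out_range = single.max() - single.min()
        assert np.median(diff) < 1e-9
        assert np.quantile(diff, 0.9) < 0.01 * out_range
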