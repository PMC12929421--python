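"""Splitting, label encoding, augmentation and normalization contracts."""

import numpy as np
import pytest

from phenoseg import datasetio as dio
from phenoseg.synthfield import TilePair


def make_pair(mask, image=None):
    if image is None:
        rng = np.random.default_rng(0)
        image = rng.integers(0, 256, mask.shape + (3,), dtype=np.uint8)
    cov = int((mask == 255).sum()) / mask.size
    return TilePair(image=image, mask=mask, true_coverage=cov)


class TestSplitDataset:
    def test_600_ids_split_480_60_60(self):
        m = dio.split_dataset([f"s{i}" for i in range(600)], seed=1)
        assert (len(m.train), len(m.val), len(m.test)) == (480, 60, 60)

    def test_10_ids_split_8_1_1(self):
        m = dio.split_dataset([f"s{i}" for i in range(10)], seed=1)
        assert (len(m.train), len(m.val), len(m.test)) == (8, 1, 1)

    def test_partition_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(37)]
        m = dio.split_dataset(ids, seed=3)
        union = set(m.train) | set(m.val) | set(m.test)
        assert union == set(ids)
        assert len(m.train) + len(m.val) + len(m.test) == 37

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(50)]
        a = dio.split_dataset(ids, seed=9)
        b = dio.split_dataset(ids, seed=9)
        c = dio.split_dataset(ids, seed=10)
        assert a.train == b.train and a.val == b.val and a.test == b.test
        assert a.train != c.train

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            dio.split_dataset(["a"] * 5)


class TestLabelEncoding:
    def test_all_plant_mask(self):
        mask = np.full((4, 4), 255, dtype=np.uint8)
        assert (dio.encode_label(mask) == 1).all()

    def test_encode_decode_roundtrip_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = rng.choice([0, 255], size=(16, 16)).astype(np.uint8)
            assert np.array_equal(dio.decode_label(dio.encode_label(mask)), mask)

    def test_intermediate_value_reported(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = 128
        with pytest.raises(dio.LabelFormatError, match="128"):
            dio.encode_label(mask)


class TestAugmentScale:
    def test_identity_factor_at_crop_size(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[10:20, 10:20] = 255
        pair = make_pair(mask)
        out = dio.augment_scale(pair, 1.0, crop_seed=0, crop_size=(64, 64))
        assert np.array_equal(out.image, pair.image)
        assert np.array_equal(out.mask, pair.mask)

    def test_factor_two_keeps_mask_binary_and_output_size(self):
        mask = (np.random.default_rng(1).random((64, 64)) > 0.8)
        pair = make_pair((mask * 255).astype(np.uint8))
        out = dio.augment_scale(pair, 2.0, crop_seed=3, crop_size=(64, 64))
        assert out.mask.shape == (64, 64)
        assert set(np.unique(out.mask)) <= {0, 255}

    def test_nearest_mask_resampling_equals_replication_oracle(self):
        rng = np.random.default_rng(2)
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8) * 255
        scaled = dio.resize_mask(mask, (16, 16))
        oracle = np.kron(mask, np.ones((2, 2), dtype=np.uint8))
        assert np.array_equal(scaled, oracle)

    def test_nonpositive_factor_rejected(self):
        pair = make_pair(np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(ValueError, match="positive"):
            dio.augment_scale(pair, 0.0, crop_seed=0)

    def test_upscale_from_small_tile_pads_reflectively(self):
        pair = make_pair(np.zeros((40, 40), dtype=np.uint8))
        out = dio.augment_scale(pair, 0.5, crop_seed=1, crop_size=(64, 64))
        assert out.mask.shape == (64, 64)


class TestAugmentFlip:
    def test_double_flip_is_identity(self):
        pair = make_pair((np.random.default_rng(0).random((8, 8)) > 0.5)
                         .astype(np.uint8) * 255)
        once = dio.augment_flip(pair, "horizontal")
        twice = dio.augment_flip(once, "horizontal")
        assert np.array_equal(twice.image, pair.image)
        assert np.array_equal(twice.mask, pair.mask)

    def test_flip_preserves_coverage_exactly(self):
        rng = np.random.default_rng(1)
        pair = make_pair((rng.random((12, 12)) > 0.7).astype(np.uint8) * 255)
        for axis in ("horizontal", "vertical"):
            assert dio.augment_flip(pair, axis).true_coverage == pair.true_coverage

    def test_flip_matches_index_reversal_oracle(self):
        mask = np.arange(16, dtype=np.uint8).reshape(4, 4) % 2 * 255
        pair = make_pair(mask)
        fh = dio.augment_flip(pair, "horizontal").mask
        fv = dio.augment_flip(pair, "vertical").mask
        for i in range(4):
            for j in range(4):
                assert fh[i, j] == mask[i, 3 - j]
                assert fv[i, j] == mask[3 - i, j]

    def test_apply_false_returns_input(self):
        pair = make_pair(np.zeros((4, 4), dtype=np.uint8))
        assert dio.augment_flip(pair, "vertical", apply=False) is pair

    def test_unknown_axis_rejected(self):
        pair = make_pair(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="axis"):
            dio.augment_flip(pair, "diagonal")


class TestAugmentPhotometric:
    def test_identity_parameters(self):
        rng = np.random.default_rng(0)
        image = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        assert np.array_equal(dio.augment_photometric(image, 0.0, 1.0), image)

    def test_output_clipped_to_valid_range(self):
        rng = np.random.default_rng(1)
        image = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        for d, c in [(0.2, 1.15), (-0.2, 0.85), (0.2, 0.85)]:
            out = dio.augment_photometric(image, d, c)
            assert out.min() >= 0 and out.max() <= 255

    def test_midgray_brightness_matches_scalar_formula(self):
        image = np.full((4, 4, 3), 127, dtype=np.uint8)
        out = dio.augment_photometric(image, 0.2, 1.0)
        expected = np.clip(round(127 + 0.2 * 255.0), 0, 255)
        assert (out == expected).all()

    def test_general_pixel_formula(self):
        rng = np.random.default_rng(2)
        image = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        d, c = -0.1, 1.1
        out = dio.augment_photometric(image, d, c)
        expected = np.clip(np.round(
            c * (image.astype(float) - 127.5) + 127.5 + d * 255.0), 0, 255)
        assert np.array_equal(out, expected.astype(np.uint8))

    def test_out_of_range_parameters_rejected(self):
        image = np.zeros((2, 2, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="brightness"):
            dio.augment_photometric(image, 0.3, 1.0)
        with pytest.raises(ValueError, match="contrast"):
            dio.augment_photometric(image, 0.0, 1.3)


class TestNormalize:
    def test_constant_image_with_matching_mean_is_zero(self):
        image = np.full((5, 5, 3), 50, dtype=np.uint8)
        stats = dio.NormalizationStats(mean=(50, 50, 50), std=(2, 2, 2))
        assert (dio.normalize(image, stats) == 0).all()

    def test_self_statistics_standardize(self):
        rng = np.random.default_rng(0)
        image = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        stats = dio.compute_stats([image])
        out = dio.normalize(image, stats)
        assert np.abs(out.reshape(-1, 3).mean(axis=0)).max() < 1e-5
        assert np.abs(out.reshape(-1, 3).std(axis=0) - 1).max() < 1e-5

    def test_stats_match_two_pass_recomputation(self):
        rng = np.random.default_rng(1)
        images = [rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
                  for _ in range(3)]
        stats = dio.compute_stats(images)
        flat = np.concatenate([im.reshape(-1, 3).astype(float)
                               for im in images])
        for c in range(3):
            mean = sum(flat[:, c]) / len(flat)
            var = sum((v - mean) ** 2 for v in flat[:, c]) / len(flat)
            assert abs(stats.mean[c] - mean) < 1e-6
            assert abs(stats.std[c] - np.sqrt(var)) < 1e-6

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError, match="std"):
            dio.NormalizationStats(mean=(0, 0, 0), std=(1, 0, 1))


class TestAugmentationConfig:
    def test_defaults_match_protocol(self):
        cfg = dio.AugmentationConfig()
        assert cfg.scale_levels == (0.5, 0.75, 1.25, 1.5, 1.75, 2.0)
        assert cfg.crop_size == (512, 512)
        assert cfg.flip_probability == 0.5
        assert cfg.brightness_range == 0.20
        assert cfg.contrast_range == 0.15

    def test_with_only_isolates_one_strategy(self):
        cfg = dio.AugmentationConfig().with_only("flip")
        assert cfg.enabled_strategies == ("flip",)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            dio.AugmentationConfig(enabled_strategies=("blur",))


def test_random_augment_never_breaks_mask_binarity(tiny_dataset):
    cfg = dio.AugmentationConfig(crop_size=(64, 64))
    rng = np.random.default_rng(5)
    for _ in range(20):
        pair = tiny_dataset[int(rng.integers(len(tiny_dataset)))]
        out = dio.random_augment(pair, cfg, rng)
        assert set(np.unique(out.mask)) <= {0, 255}
        assert out.mask.shape == (64, 64)


def test_geometric_augmentation_commutes_with_encoding(tiny_dataset):
    pair = tiny_dataset[0]
    flipped_then_encoded = dio.encode_label(
        dio.augment_flip(pair, "horizontal").mask)
    encoded_then_flipped = np.flip(dio.encode_label(pair.mask), axis=1)
    assert np.array_equal(flipped_then_encoded, encoded_then_flipped)


def test_save_load_roundtrip(tmp_path, tiny_dataset):
    pair = tiny_dataset[0]
    dio.save_tile(pair, tmp_path / "t.png", tmp_path / "t_mask.png")
    loaded = dio.load_tile(tmp_path / "t.png", tmp_path / "t_mask.png")
    assert np.array_equal(loaded.image, pair.image)
    assert np.array_equal(loaded.mask, pair.mask)
    assert loaded.true_coverage == pair.true_coverage
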