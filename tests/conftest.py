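"""Shared fixtures: small synthetic datasets and reference models."""

import numpy as np
import pytest

from phenoseg import synthfield as sf


@pytest.fixture(scope="session")
def small_field_spec():
    return sf.FieldSpec(tile_height=64, tile_width=64, plant_density=4, seed=11)


@pytest.fixture(scope="session")
def small_tile(small_field_spec):
    return sf.generate_tile(small_field_spec)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Thirty 64x64 tiles for dataset-level tests (split/training smoke)."""
    seeds = np.random.SeedSequence(77).generate_state(30)
    return [sf.generate_tile(
        sf.FieldSpec(tile_height=64, tile_width=64, plant_density=4,
                     seed=int(s % 2 ** 31)), plot_id=f"t{i:03d}")
        for i, s in enumerate(seeds)]


@pytest.fixture(scope="session")
def planted_table():
    """The documented planted feature table (200 plots, 4 informative
    with |r| > 0.8 by construction, 26 noise columns, seed 0)."""
    return sf.generate_feature_table(sf.SyntheticFeatureSpec(seed=0))


class PixelwiseGreenness:
    """A 1x1-receptive-field reference model: class = green excess threshold.

    Satisfies the Segmenter protocol (predict_proba / size_multiple /
    num_classes) without any learned weights, so window content and flips
    cannot change per-pixel decisions.
    """

    size_multiple = 1
    num_classes = 2

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        img = image.astype(np.float64)
        green_excess = 2 * img[:, :, 1] - img[:, :, 0] - img[:, :, 2]
        p_plant = 1.0 / (1.0 + np.exp(-(green_excess - 40.0) / 10.0))
        return np.stack([1.0 - p_plant, p_plant])


@pytest.fixture(scope="session")
def pixelwise_model():
    return PixelwiseGreenness()
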