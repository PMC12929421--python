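"""Dataset construction: label encoding, 8:1:1 splitting, normalization and
the three training-time augmentation families (scale+crop, flips,
photometric distortion).

Conventions: images are (H, W, 3) uint8, masks (H, W) uint8 in {0, 255};
coordinates are row-major, 0-based, origin top-left. Images are resampled
bilinearly, masks by nearest neighbour so labels stay binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize

from .synthfield import TilePair

__all__ = [
    "AugmentationConfig",
    "SplitManifest",
    "NormalizationStats",
    "split_dataset",
    "encode_label",
    "decode_label",
    "augment_scale",
    "augment_flip",
    "augment_photometric",
    "augment_saturation",
    "normalize",
    "compute_stats",
    "save_tile",
    "load_tile",
]

DEFAULT_SCALE_LEVELS = (0.5, 0.75, 1.25, 1.5, 1.75, 2.0)


class LabelFormatError(ValueError):
    """Mask contains values other than {0, 255}."""


@dataclass
class AugmentationConfig:
    """Training-time augmentation settings.

    Defaults mirror the common field-imaging recipe: six scale levels with a
    512x512 crop, both flips at probability 0.5, and photometric jitter of
    ±20% brightness / ±15% contrast. Saturation jitter is available but not
    part of the ablation preset, which enables brightness/contrast only.
    """

    scale_levels: tuple[float, ...] = DEFAULT_SCALE_LEVELS
    crop_size: tuple[int, int] = (512, 512)
    flip_probability: float = 0.5
    flip_axes: tuple[str, ...] = ("horizontal", "vertical")
    brightness_range: float = 0.20
    contrast_range: float = 0.15
    saturation_range: float = 0.0
    enabled_strategies: tuple[str, ...] = ("scale", "flip", "photometric")

    def __post_init__(self) -> None:
        known = {"scale", "flip", "photometric"}
        bad = set(self.enabled_strategies) - known
        if bad:
            raise ValueError(f"unknown augmentation strategies: {sorted(bad)}")
        if not 0 <= self.flip_probability <= 1:
            raise ValueError("flip_probability must be in [0, 1]")
        if any(s <= 0 for s in self.scale_levels):
            raise ValueError("scale levels must be positive")

    def with_only(self, strategy: str) -> "AugmentationConfig":
        """Single-strategy preset for the augmentation ablation."""
        cfg = AugmentationConfig(**asdict(self))
        cfg.enabled_strategies = (strategy,)
        return cfg


@dataclass
class SplitManifest:
    train: list[str]
    val: list[str]
    test: list[str]
    ratio: tuple[int, int, int] = (8, 1, 1)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"train": self.train, "val": self.val, "test": self.test,
             "ratio": list(self.ratio), "seed": self.seed}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        return cls(train=d["train"], val=d["val"], test=d["test"],
                   ratio=tuple(d["ratio"]), seed=d["seed"])


@dataclass
class NormalizationStats:
    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std):
            raise ValueError(f"std must be > 0 per channel, got {self.std}")


def split_dataset(sample_ids: list[str], ratio: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> SplitManifest:
    """Shuffle with ``seed`` and partition into train/val/test.

    Val and test sizes are floored from the ratio; the remainder goes to
    train, so the partition is disjoint and exhaustive.
    """
    n = len(sample_ids)
    if n < 10:
        raise ValueError(f"need >= 10 samples for a non-degenerate split, got {n}")
    rng = np.random.default_rng(seed)
    order = list(np.array(sample_ids, dtype=object)[rng.permutation(n)])
    total = sum(ratio)
    n_val = max(1, n * ratio[1] // total)
    n_test = max(1, n * ratio[2] // total)
    n_train = n - n_val - n_test
    return SplitManifest(train=order[:n_train],
                         val=order[n_train:n_train + n_val],
                         test=order[n_train + n_val:],
                         ratio=ratio, seed=seed)


def encode_label(mask: np.ndarray) -> np.ndarray:
    """{0, 255} mask -> {0, 1} class map (plant = 1)."""
    values = np.unique(mask)
    bad = set(values.tolist()) - {0, 255}
    if bad:
        raise LabelFormatError(
            f"mask must contain only {{0, 255}}, found extra values {sorted(bad)}")
    return (mask == 255).astype(np.uint8)


def decode_label(class_map: np.ndarray) -> np.ndarray:
    """{0, 1} class map -> {0, 255} mask; exact inverse of encode_label."""
    values = set(np.unique(class_map).tolist())
    if values - {0, 1}:
        raise LabelFormatError(
            f"class map must contain only {{0, 1}}, found {sorted(values)}")
    return (class_map.astype(np.uint8)) * 255


def _nearest_indices(n_out: int, n_in: int) -> np.ndarray:
    centers = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    return np.clip(np.round(centers).astype(int), 0, n_in - 1)


def resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an 8-bit image, back to uint8."""
    out = _sk_resize(image.astype(np.float64), shape, order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize via explicit index mapping (stays binary)."""
    iy = _nearest_indices(shape[0], mask.shape[0])
    ix = _nearest_indices(shape[1], mask.shape[1])
    return mask[np.ix_(iy, ix)]


def _pad_reflect_to(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    ph = max(0, h - arr.shape[0])
    pw = max(0, w - arr.shape[1])
    if ph == 0 and pw == 0:
        return arr
    pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
    if arr.ndim == 3:
        pad.append((0, 0))
    return np.pad(arr, pad, mode="reflect")


def augment_scale(pair: TilePair, factor: float, crop_seed: int,
                  crop_size: tuple[int, int] = (512, 512)) -> TilePair:
    """Rescale by ``factor`` then take a seeded random crop of ``crop_size``.

    The image is resampled bilinearly, the mask by nearest neighbour; if the
    scaled tile is smaller than the crop it is padded reflectively first.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    h, w = pair.mask.shape
    nh, nw = max(1, round(h * factor)), max(1, round(w * factor))
    image = resize_image(pair.image, (nh, nw)) if (nh, nw) != (h, w) else pair.image
    mask = resize_mask(pair.mask, (nh, nw)) if (nh, nw) != (h, w) else pair.mask
    ch, cw = crop_size
    image = _pad_reflect_to(image, ch, cw)
    mask = _pad_reflect_to(mask, ch, cw)
    rng = np.random.default_rng(crop_seed)
    y0 = int(rng.integers(0, image.shape[0] - ch + 1))
    x0 = int(rng.integers(0, image.shape[1] - cw + 1))
    image = image[y0:y0 + ch, x0:x0 + cw]
    mask = mask[y0:y0 + ch, x0:x0 + cw]
    cov = int((mask == 255).sum()) / mask.size
    return TilePair(image=image.copy(), mask=mask.copy(),
                    true_coverage=cov, plot_id=pair.plot_id)


def augment_flip(pair: TilePair, axis: str, apply: bool = True) -> TilePair:
    """Flip image and mask together along 'horizontal' or 'vertical'."""
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    if not apply:
        return pair
    ax = 1 if axis == "horizontal" else 0
    return TilePair(image=np.flip(pair.image, axis=ax).copy(),
                    mask=np.flip(pair.mask, axis=ax).copy(),
                    true_coverage=pair.true_coverage, plot_id=pair.plot_id)


def augment_photometric(image: np.ndarray, brightness_delta: float,
                        contrast_factor: float, *, mid: float = 127.5,
                        value_range: float = 255.0) -> np.ndarray:
    """pixel' = clip(contrast*(pixel - mid) + mid + brightness*range).

    ``brightness_delta`` is a fraction of the full value range (|d| <= 0.20);
    ``contrast_factor`` lies in [0.85, 1.15].
    """
    if abs(brightness_delta) > 0.20 + 1e-12:
        raise ValueError(f"|brightness_delta| must be <= 0.20, got {brightness_delta}")
    if not 0.85 - 1e-12 <= contrast_factor <= 1.15 + 1e-12:
        raise ValueError(f"contrast_factor must be in [0.85, 1.15], got {contrast_factor}")
    out = (contrast_factor * (image.astype(np.float64) - mid) + mid
           + brightness_delta * value_range)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def augment_saturation(image: np.ndarray, factor: float) -> np.ndarray:
    """Optional HSV saturation scale (±15% preset); not in the ablation set."""
    if not 0.85 - 1e-12 <= factor <= 1.15 + 1e-12:
        raise ValueError(f"saturation factor must be in [0.85, 1.15], got {factor}")
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(image)
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] * factor, 0, 1)
    return np.clip(np.round(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)


def compute_stats(images: list[np.ndarray]) -> NormalizationStats:
    """Per-channel mean/std over a list of (H, W, 3) uint8 images."""
    stacked = np.concatenate([im.reshape(-1, 3).astype(np.float64)
                              for im in images], axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)
    return NormalizationStats(mean=tuple(mean), std=tuple(std))


def normalize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """(pixel - mean)/std per channel -> float32 (H, W, 3)."""
    mean = np.asarray(stats.mean, dtype=np.float64)
    std = np.asarray(stats.std, dtype=np.float64)
    return ((image.astype(np.float64) - mean) / std).astype(np.float32)


def random_augment(pair: TilePair, config: AugmentationConfig,
                   rng: np.random.Generator,
                   crop_size: tuple[int, int] | None = None) -> TilePair:
    """Draw one augmented sample according to the enabled strategies."""
    crop = crop_size or config.crop_size
    if "scale" in config.enabled_strategies:
        factor = float(rng.choice(config.scale_levels))
        pair = augment_scale(pair, factor, int(rng.integers(2 ** 31)), crop)
    elif pair.mask.shape != tuple(crop):
        pair = augment_scale(pair, 1.0, int(rng.integers(2 ** 31)), crop)
    if "flip" in config.enabled_strategies:
        for axis in config.flip_axes:
            if rng.uniform() < config.flip_probability:
                pair = augment_flip(pair, axis)
    if "photometric" in config.enabled_strategies:
        image = augment_photometric(
            pair.image,
            float(rng.uniform(-config.brightness_range, config.brightness_range)),
            float(rng.uniform(1 - config.contrast_range, 1 + config.contrast_range)))
        if config.saturation_range > 0:
            image = augment_saturation(
                image, float(rng.uniform(1 - config.saturation_range,
                                         1 + config.saturation_range)))
        pair = TilePair(image=image, mask=pair.mask,
                        true_coverage=pair.true_coverage, plot_id=pair.plot_id)
    return pair


def save_tile(pair: TilePair, image_path: str | Path, mask_path: str | Path) -> None:
    iio.imwrite(Path(image_path), pair.image)
    iio.imwrite(Path(mask_path), pair.mask)


def load_tile(image_path: str | Path, mask_path: str | Path,
              plot_id: str = "") -> TilePair:
    image = np.asarray(iio.imread(Path(image_path)))
    mask = np.asarray(iio.imread(Path(mask_path)))
    if mask.ndim == 3:
        mask = mask[:, :, 0]
    encode_label(mask)  # validates {0, 255}
    cov = int((mask == 255).sum()) / mask.size
    return TilePair(image=image, mask=mask, true_coverage=cov, plot_id=plot_id)
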