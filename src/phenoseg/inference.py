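"""Test-time augmentation and sliding-window prediction.

Long plot strips do not fit a fixed-size network input, so prediction runs
a window (default 512x512, stride 256) across the strip, accumulating
softmax probabilities and a coverage-count map; overlaps are fused by
probability averaging, which smooths window seams. TTA averages softmax
probabilities over multi-scale and horizontally flipped variants after
inverting each transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .datasetio import NormalizationStats, normalize
from .models import SegmentationModel

__all__ = [
    "TTAConfig",
    "WindowConfig",
    "Segmenter",
    "predict_tta",
    "predict_sliding",
]


@dataclass
class TTAConfig:
    scales: tuple[float, ...] = (0.75, 1.0, 1.25)
    horizontal_flip: bool = True

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("TTA scales must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ValueError(f"TTA scales must be positive, got {self.scales}")


@dataclass
class WindowConfig:
    window: tuple[int, int] = (512, 512)
    stride: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        for axis in (0, 1):
            if self.stride[axis] <= 0:
                raise ValueError(f"stride must be positive, got {self.stride}")
            if self.stride[axis] > self.window[axis]:
                raise ValueError(
                    f"stride {self.stride} must not exceed window {self.window}")


class Segmenter:
    """A trained model plus its normalization statistics.

    ``predict_proba`` maps a raw (H, W, 3) uint8 image to per-class softmax
    probabilities (num_classes, H, W). Any object with ``predict_proba``,
    ``size_multiple`` and ``num_classes`` can stand in (e.g. pixelwise
    reference models in tests).
    """

    def __init__(self, model: SegmentationModel, stats: NormalizationStats) -> None:
        self.model = model
        self.stats = stats

    @property
    def size_multiple(self) -> int:
        return self.model.size_multiple

    @property
    def num_classes(self) -> int:
        return self.model.config.num_classes

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        x = normalize(image, self.stats).transpose(2, 0, 1)[None]
        logits = self.model.predict_logits(x)[0]
        shifted = logits - logits.max(axis=0, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=0, keepdims=True)


def _round_to_multiple(value: int, multiple: int) -> int:
    return max(multiple, int(round(value / multiple)) * multiple)


def _resize_probs(probs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if probs.shape[1:] == shape:
        return probs
    out = np.stack([_sk_resize(p, shape, order=1, mode="reflect",
                               anti_aliasing=False, preserve_range=True)
                    for p in probs])
    return out / out.sum(axis=0, keepdims=True)


def predict_tta(segmenter, image: np.ndarray,
                tta: TTAConfig | None = None, *,
                return_proba: bool = False) -> np.ndarray:
    """Average softmax probabilities over (scale, flip) variants.

    Each variant is forward-passed, its probabilities un-flipped and
    resampled back to the native resolution, then averaged; the class map is
    the argmax of the mean. Scales that would shrink the image below the
    model's minimum input are skipped with a warning.
    """
    tta = tta or TTAConfig()
    h, w = image.shape[:2]
    m = segmenter.size_multiple
    flips = [False, True] if tta.horizontal_flip else [False]

    acc = None
    n_used = 0
    for scale in tta.scales:
        if round(h * scale) < m or round(w * scale) < m:
            warnings.warn(f"TTA scale {scale} shrinks image below the "
                          f"model minimum {m}; variant skipped")
            continue
        if scale == 1.0 and h % m == 0 and w % m == 0:
            nh, nw = h, w
        else:
            nh = _round_to_multiple(round(h * scale), m)
            nw = _round_to_multiple(round(w * scale), m)
        if (nh, nw) != (h, w):
            from .datasetio import resize_image
            variant = resize_image(image, (nh, nw))
        else:
            variant = image
        for flip in flips:
            vimg = variant[:, ::-1] if flip else variant
            probs = segmenter.predict_proba(np.ascontiguousarray(vimg))
            if flip:
                probs = probs[:, :, ::-1]
            probs = _resize_probs(probs, (h, w))
            acc = probs if acc is None else acc + probs
            n_used += 1
    if acc is None:
        raise ValueError("all TTA variants were skipped; image too small")
    mean = acc / n_used
    if return_proba:
        return mean
    return mean.argmax(axis=0).astype(np.uint8)


def predict_sliding(segmenter, strip: np.ndarray,
                    window: WindowConfig | None = None,
                    tta: TTAConfig | None = None, *,
                    return_proba: bool = False) -> np.ndarray:
    """Sliding-window prediction over an arbitrarily large image.

    Windows are placed at stride offsets with the final window snapped to
    the border, so every pixel is covered at least once; per-pixel
    probabilities are averaged over overlapping windows. If the strip is
    smaller than the window it is padded reflectively and cropped back.
    """
    window = window or WindowConfig()
    h, w = strip.shape[:2]
    wh, ww = window.window
    ph, pw = max(0, wh - h), max(0, ww - w)
    padded = strip
    if ph or pw:
        padded = np.pad(strip, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    hh, wwd = padded.shape[:2]

    def starts(dim: int, win: int, stride: int) -> list[int]:
        s = list(range(0, dim - win + 1, stride))
        if s[-1] != dim - win:
            s.append(dim - win)
        return s

    n_classes = segmenter.num_classes
    acc = np.zeros((n_classes, hh, wwd), dtype=np.float64)
    count = np.zeros((hh, wwd), dtype=np.float64)
    for y0 in starts(hh, wh, window.stride[0]):
        for x0 in starts(wwd, ww, window.stride[1]):
            tile = padded[y0:y0 + wh, x0:x0 + ww]
            if tta is not None:
                probs = predict_tta(segmenter, tile, tta, return_proba=True)
            else:
                probs = segmenter.predict_proba(tile)
            acc[:, y0:y0 + wh, x0:x0 + ww] += probs
            count[y0:y0 + wh, x0:x0 + ww] += 1.0
    assert count.min() >= 1.0
    probs = (acc / count)[:, :h, :w]
    if return_proba:
        return probs
    return probs.argmax(axis=0).astype(np.uint8)
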