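"""Remote-sensing feature extraction over plant-masked regions.

Band symbols denote *average reflectance over the plant mask* — features
are computed on mask-mean band values (means first, then formula). The
battery covers visible-band indices (RGRI, NGRDI, VARI, MGVRI, GRVI, NDGI,
ExG, ExR, ExGR, COM), red-edge/NIR indices (NDRE, GNDVI, GRNDVI) and
color-space statistics (mean hue H, mean HSV saturation S, mean CIELab a*).

COM combines ExG, ExGR, CIVE and VEG with weights 0.25/0.3/0.33/0.12,
where CIVE = 0.441 R - 0.811 G + 0.385 B + 18.78745 and
VEG = G / (R^0.667 * B^0.333) are the canonical published definitions.
GRNDVI is implemented as (NIR - (G + R)) / (NIR + (G + R)).

Zero denominators yield NaN with a per-feature validity flag rather than a
fabricated value. A per-pixel-then-average mode is available for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv, rgb2lab

__all__ = [
    "BandStack",
    "ColorStats",
    "FeatureVector",
    "band_means",
    "rgb_indices",
    "nir_indices",
    "color_stats",
    "extract_features",
    "RGB_FEATURES",
    "NIR_FEATURES",
]

RGB_FEATURES = ("B", "G", "RGRI", "NGRDI", "VARI", "MGVRI", "GRVI", "NDGI",
                "ExG", "ExR", "ExGR", "COM")
COLOR_FEATURES = ("H", "S", "a")
NIR_FEATURES = ("NDRE", "GNDVI", "GRNDVI")


class EmptyMaskError(ValueError):
    """The plant mask contains no pixels; masked means are undefined."""


@dataclass
class BandStack:
    """Mask-mean reflectances in [0, 1]; RE/NIR are None for RGB-only input."""

    R: float
    G: float
    B: float
    RE: float | None
    NIR: float | None
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count <= 0:
            raise EmptyMaskError("pixel_count must be > 0")

    @property
    def has_nir(self) -> bool:
        return self.RE is not None and self.NIR is not None


@dataclass
class ColorStats:
    H: float      # mean hue over mask, HSV convention in [0, 1)
    S: float      # mean HSV saturation over mask, [0, 1]
    a: float      # mean CIELab a* over mask (D65); negative = green side


@dataclass
class FeatureVector:
    values: dict[str, float]
    valid: dict[str, bool]
    nir_available: bool = True

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    values = set(np.unique(mask).tolist())
    if values <= {0, 1}:
        return mask.astype(bool)
    if values <= {0, 255}:
        return mask == 255
    raise ValueError(f"mask must be binary ({{0,1}} or {{0,255}}), got {sorted(values)}")


def band_means(stack: np.ndarray, mask: np.ndarray) -> BandStack:
    """Arithmetic mean of each band over mask pixels.

    ``stack`` is (H, W, 5) float in band order (R, G, B, RE, NIR), or
    (H, W, 3) for RGB-only data (reflectances in [0, 1], or 8-bit values
    which are rescaled by 1/255).
    """
    m = _as_bool_mask(mask)
    if not m.any():
        raise EmptyMaskError("plant mask is empty; band means are undefined")
    data = np.asarray(stack, dtype=np.float64)
    if data.ndim != 3 or data.shape[2] not in (3, 5):
        raise ValueError(f"expected (H, W, 3) or (H, W, 5) stack, got {data.shape}")
    if data.max() > 1.0:
        data = data / 255.0
    means = data[m].mean(axis=0)
    re_mean = float(means[3]) if data.shape[2] == 5 else None
    nir_mean = float(means[4]) if data.shape[2] == 5 else None
    return BandStack(R=float(means[0]), G=float(means[1]), B=float(means[2]),
                     RE=re_mean, NIR=nir_mean, pixel_count=int(m.sum()))


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def rgb_indices(bands: BandStack) -> dict[str, float]:
    """Visible-band vegetation/color indices from mask-mean reflectances."""
    r, g, b = bands.R, bands.G, bands.B
    exg = 2 * g - r - b
    exr = 1.4 * r - g
    exgr = exg - exr
    cive = 0.441 * r - 0.811 * g + 0.385 * b + 18.78745
    veg = _ratio(g, r ** 0.667 * b ** 0.333) if r > 0 and b > 0 else float("nan")
    ngrdi = _ratio(g - r, g + r)
    return {
        "B": b,
        "G": g,
        "RGRI": _ratio(r, g),
        "NGRDI": ngrdi,
        "VARI": _ratio(g - r, g + r - b),
        "MGVRI": _ratio(g ** 2 - r ** 2, g ** 2 + r ** 2),
        "GRVI": ngrdi,
        "NDGI": ngrdi,
        "ExG": exg,
        "ExR": exr,
        "ExGR": exgr,
        "COM": 0.25 * exg + 0.3 * exgr + 0.33 * cive + 0.12 * veg,
    }


def nir_indices(bands: BandStack) -> dict[str, float]:
    """Red-edge / NIR indices; requires a 5-band stack."""
    if not bands.has_nir:
        raise ValueError("BandStack has no RE/NIR means; use a 5-band stack")
    r, g = bands.R, bands.G
    re_, nir = bands.RE, bands.NIR
    return {
        "NDRE": _ratio(nir - re_, nir + re_),
        "GNDVI": _ratio(nir - g, nir + g),
        "GRNDVI": _ratio(nir - (g + r), nir + (g + r)),
    }


def color_stats(image: np.ndarray, mask: np.ndarray) -> ColorStats:
    """Mean hue, saturation and CIELab a* over the plant mask.

    ``image`` is (H, W, 3) uint8 or float RGB in [0, 1]; conversions use the
    standard sRGB->HSV and sRGB->CIELab (D65) transforms.
    """
    m = _as_bool_mask(mask)
    if not m.any():
        raise EmptyMaskError("plant mask is empty; color statistics undefined")
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    hsv = rgb2hsv(img)
    lab = rgb2lab(img)
    return ColorStats(H=float(hsv[:, :, 0][m].mean()),
                      S=float(hsv[:, :, 1][m].mean()),
                      a=float(lab[:, :, 1][m].mean()))


def extract_features(image: np.ndarray, mask: np.ndarray,
                     stack: np.ndarray | None = None, *,
                     per_pixel: bool = False) -> FeatureVector:
    """Assemble the full named feature vector for one plot.

    ``image`` is the RGB tile (required); ``stack`` an optional co-registered
    (H, W, 5) reflectance stack enabling the NIR indices. With
    ``per_pixel=True`` the band indices are computed per pixel and then
    averaged over the mask instead of the default means-first mode.
    """
    source = stack if stack is not None else image
    values: dict[str, float] = {}
    if per_pixel:
        m = _as_bool_mask(mask)
        if not m.any():
            raise EmptyMaskError("plant mask is empty")
        data = np.asarray(source, dtype=np.float64)
        if data.max() > 1.0:
            data = data / 255.0
        acc: dict[str, list[float]] = {}
        px = data[m]
        for row in px:
            bs = BandStack(R=row[0], G=row[1], B=row[2],
                           RE=row[3] if row.shape[0] == 5 else None,
                           NIR=row[4] if row.shape[0] == 5 else None,
                           pixel_count=1)
            for k, v in rgb_indices(bs).items():
                acc.setdefault(k, []).append(v)
            if bs.has_nir:
                for k, v in nir_indices(bs).items():
                    acc.setdefault(k, []).append(v)
        values.update({k: float(np.mean(v)) for k, v in acc.items()})
        bands = band_means(source, mask)
    else:
        bands = band_means(source, mask)
        values.update(rgb_indices(bands))
        if bands.has_nir:
            values.update(nir_indices(bands))
    cs = color_stats(image, mask)
    values["H"], values["S"], values["a"] = cs.H, cs.S, cs.a
    nir_available = bands.has_nir
    valid = {k: bool(np.isfinite(v)) for k, v in values.items()}
    return FeatureVector(values=values, valid=valid,
                         nir_available=nir_available)
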