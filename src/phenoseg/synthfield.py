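"""Synthetic UAV-like field imagery and feature tables with known ground truth.

The generator emulates nadir RGB views of seedling-stage row crops on bare
soil: small irregular green canopies (unions of perturbed ellipses) scattered
over a textured brown soil background, with a smooth illumination gradient
and optional cast shadows next to plants. Masks are exact by construction,
so every downstream stage (training, coverage, features, selection) can be
validated against bit-level ground truth without any external dataset.

Reflectance stacks add red-edge and near-infrared bands in which vegetation
is bright (NIR > R over plant pixels), mimicking the red-edge behaviour of
healthy canopies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FieldSpec",
    "TilePair",
    "MultispectralTile",
    "SyntheticFeatureSpec",
    "FeatureTable",
    "generate_tile",
    "generate_strip",
    "generate_multispectral",
    "generate_feature_table",
]

BAND_ORDER = ("R", "G", "B", "RE", "NIR")


class FieldSpecError(ValueError):
    """Invalid field specification; the message names the offending field."""


@dataclass
class FieldSpec:
    """Parameters of the synthetic field image generator.

    Defaults describe a seedling-stage canopy: sparse small plants
    (expected ~12 per 128 px tile, radii 3-8 px), strong foliage/soil color
    separation, mild vignetting-style illumination gradient and occasional
    shadows.
    """

    tile_height: int = 128
    tile_width: int = 128
    plant_density: float = 12.0
    blob_radius_range: tuple[float, float] = (3.0, 8.0)
    plant_color_mean: tuple[float, float, float] = (52.0, 120.0, 58.0)
    plant_color_sd: float = 10.0
    soil_color_mean: tuple[float, float, float] = (138.0, 102.0, 72.0)
    soil_color_sd: float = 13.0
    soil_texture_scale: int = 16
    illumination_gradient_amplitude: float = 0.25
    shadow_probability: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.tile_height < 32:
            raise FieldSpecError(f"tile_height must be >= 32, got {self.tile_height}")
        if self.tile_width < 32:
            raise FieldSpecError(f"tile_width must be >= 32, got {self.tile_width}")
        if self.plant_density < 0:
            raise FieldSpecError(f"plant_density must be >= 0, got {self.plant_density}")
        rmin, rmax = self.blob_radius_range
        if not (0 < rmin <= rmax):
            raise FieldSpecError(
                f"blob_radius_range must satisfy 0 < min <= max, got {self.blob_radius_range}")
        if not 0.0 <= self.illumination_gradient_amplitude <= 1.0:
            raise FieldSpecError(
                "illumination_gradient_amplitude must be in [0, 1], got "
                f"{self.illumination_gradient_amplitude}")
        if not 0.0 <= self.shadow_probability <= 1.0:
            raise FieldSpecError(
                f"shadow_probability must be in [0, 1], got {self.shadow_probability}")
        if self.soil_texture_scale < 1:
            raise FieldSpecError(
                f"soil_texture_scale must be >= 1, got {self.soil_texture_scale}")


@dataclass
class TilePair:
    """An RGB tile with its exact binary plant mask (background 0, plant 255)."""

    image: np.ndarray              # (H, W, 3) uint8
    mask: np.ndarray               # (H, W) uint8 in {0, 255}
    true_coverage: float           # count(mask==255) / (H*W), exact
    plot_id: str = ""

    def __post_init__(self) -> None:
        bad = set(np.unique(self.mask)) - {0, 255}
        if bad:
            raise ValueError(f"mask contains values outside {{0, 255}}: {sorted(bad)}")


@dataclass
class MultispectralTile:
    """A 5-band reflectance stack (R, G, B, RE, NIR) with its plant mask."""

    bands: np.ndarray              # (H, W, 5) float32 in [0, 1]
    mask: np.ndarray               # (H, W) uint8 in {0, 255}
    true_coverage: float
    band_order: tuple[str, ...] = BAND_ORDER
    plot_id: str = ""


def _value_noise(rng: np.random.Generator, h: int, w: int, scale: int) -> np.ndarray:
    """Smoothed random field in roughly [-1, 1] with correlation length ~scale."""
    gh = max(2, h // scale + 2)
    gw = max(2, w // scale + 2)
    coarse = rng.standard_normal((gh, gw))
    zoomed = ndimage.zoom(coarse, (h / gh, w / gw), order=3, mode="reflect",
                          grid_mode=True)
    zoomed = zoomed[:h, :w]
    return np.clip(zoomed / 2.5, -1.0, 1.0)


def _paint_blob(mask: np.ndarray, rng: np.random.Generator,
                cy: float, cx: float, radius: float) -> None:
    """Union of 3 randomly perturbed ellipses around (cy, cx)."""
    h, w = mask.shape
    for _ in range(3):
        ry = radius * rng.uniform(0.55, 1.0)
        rx = radius * rng.uniform(0.55, 1.0)
        theta = rng.uniform(0, np.pi)
        oy = cy + rng.normal(0, radius * 0.25)
        ox = cx + rng.normal(0, radius * 0.25)
        r_ext = int(np.ceil(max(ry, rx))) + 1
        y0, y1 = int(np.floor(oy)) - r_ext, int(np.ceil(oy)) + r_ext + 1
        x0, x1 = int(np.floor(ox)) - r_ext, int(np.ceil(ox)) + r_ext + 1
        y0c, y1c = max(0, y0), min(h, y1)
        x0c, x1c = max(0, x0), min(w, x1)
        if y0c >= y1c or x0c >= x1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        dy, dx = yy - oy, xx - ox
        ct, st = np.cos(theta), np.sin(theta)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        mask[y0c:y1c, x0c:x1c] |= inside


def _shadow_region(mask_bool: np.ndarray, rng: np.random.Generator,
                   cy: float, cx: float, radius: float) -> np.ndarray:
    """Half-annulus adjacent to a blob, on a random sun-opposite side."""
    h, w = mask_bool.shape
    angle = rng.uniform(0, 2 * np.pi)
    oy = cy + np.sin(angle) * radius * 1.1
    ox = cx + np.cos(angle) * radius * 1.1
    yy, xx = np.ogrid[:h, :w]
    d2 = (yy - oy) ** 2 + (xx - ox) ** 2
    region = (d2 <= (1.4 * radius) ** 2) & ~mask_bool
    return region


def _render(spec: FieldSpec, rng: np.random.Generator, mask: np.ndarray,
            centers: list[tuple[float, float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize an image for a given boolean plant mask; returns (u8 image,
    u8 mask). Shadows are drawn next to ``centers`` on soil only."""
    h, w = mask.shape
    texture = _value_noise(rng, h, w, spec.soil_texture_scale)
    image = np.empty((h, w, 3), dtype=np.float64)
    soil = np.asarray(spec.soil_color_mean)
    for c in range(3):
        image[:, :, c] = (soil[c] + texture * spec.soil_color_sd
                          + rng.normal(0, spec.soil_color_sd * 0.35, (h, w)))

    shadow = np.zeros((h, w), dtype=bool)
    for cy, cx, r in centers:
        if rng.uniform() < spec.shadow_probability:
            shadow |= _shadow_region(mask, rng, cy, cx, r)
    image[shadow] *= 0.62

    plant = np.asarray(spec.plant_color_mean)
    n_plant = int(mask.sum())
    if n_plant:
        tint = rng.normal(0, spec.plant_color_sd, (n_plant, 3))
        image[mask] = plant[None, :] + tint

    amp = spec.illumination_gradient_amplitude
    if amp > 0:
        direction = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[:h, :w]
        ramp = (np.cos(direction) * xx / max(w - 1, 1)
                + np.sin(direction) * yy / max(h - 1, 1))
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
        image *= (1.0 - amp / 2.0 + amp * ramp)[:, :, None]

    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return image, mask.astype(np.uint8) * 255


def generate_tile(spec: FieldSpec, plot_id: str = "") -> TilePair:
    """Generate one RGB tile + exact mask; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.tile_height, spec.tile_width
    n_blobs = rng.poisson(spec.plant_density) if spec.plant_density > 0 else 0
    rmin, rmax = spec.blob_radius_range
    centers = [(rng.uniform(0, h), rng.uniform(0, w), rng.uniform(rmin, rmax))
               for _ in range(n_blobs)]
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, r in centers:
        _paint_blob(mask, rng, cy, cx, r)
    image, mask_u8 = _render(spec, rng, mask, centers)
    coverage = int((mask_u8 == 255).sum()) / (h * w)
    return TilePair(image=image, mask=mask_u8, true_coverage=coverage,
                    plot_id=plot_id)


def generate_strip(spec: FieldSpec, strip_width: int,
                   target_coverage: float, plot_id: str = "") -> TilePair:
    """Generate a long plot strip whose realized coverage is within ±0.02 of
    ``target_coverage`` (verified by exact pixel count)."""
    spec.validate()
    if strip_width < spec.tile_width:
        raise FieldSpecError(
            f"strip_width must be >= tile_width ({spec.tile_width}), got {strip_width}")
    if not 0.0 <= target_coverage <= 0.9:
        raise FieldSpecError(
            "target_coverage must be in [0, 0.9] (seedling-stage canopies do "
            f"not reach closed cover), got {target_coverage}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.tile_height, strip_width
    rmin, rmax = spec.blob_radius_range

    mask = np.zeros((h, w), dtype=bool)
    centers: list[tuple[float, float, float]] = []
    total = h * w
    # Add blobs one at a time against a live mask so overlap cannot push the
    # realized coverage off target; shrink radii as the target approaches.
    while target_coverage > 0:
        cov = mask.sum() / total
        remaining = target_coverage - cov
        if remaining <= 0.5 * np.pi * rmin ** 2 / total:
            break
        r_cap = np.sqrt(remaining * total / np.pi)
        r = rng.uniform(rmin, max(rmin, min(rmax, r_cap)))
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        _paint_blob(mask, rng, cy, cx, r)
        centers.append((cy, cx, r))

    image, mask_u8 = _render(spec, rng, mask, centers)
    coverage = int((mask_u8 == 255).sum()) / total
    if target_coverage > 0 and abs(coverage - target_coverage) > 0.02:
        raise RuntimeError(
            f"strip generation missed target coverage: {coverage:.4f} vs "
            f"{target_coverage:.4f}")
    return TilePair(image=image, mask=mask_u8, true_coverage=coverage,
                    plot_id=plot_id)


def generate_multispectral(spec: FieldSpec, plot_id: str = "") -> MultispectralTile:
    """5-band reflectance stack; plant pixels have NIR > R by construction."""
    tile = generate_tile(spec, plot_id=plot_id)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5]))
    h, w = tile.mask.shape
    plant = tile.mask == 255
    rgb = tile.image.astype(np.float64) / 255.0

    re = np.where(plant,
                  rng.normal(0.42, 0.03, (h, w)),
                  rng.normal(0.27, 0.03, (h, w)))
    nir = np.where(plant,
                   rng.normal(0.65, 0.04, (h, w)),
                   rng.normal(0.28, 0.04, (h, w)))
    # enforce the red-edge contract pixelwise: NIR strictly above R on plants
    nir = np.where(plant, np.maximum(nir, rgb[:, :, 0] + 0.05), nir)
    bands = np.stack([rgb[:, :, 0], rgb[:, :, 1], rgb[:, :, 2],
                      np.clip(re, 0, 1), np.clip(nir, 0, 1)], axis=-1)
    return MultispectralTile(bands=bands.astype(np.float32), mask=tile.mask,
                             true_coverage=tile.true_coverage, plot_id=plot_id)


@dataclass
class SyntheticFeatureSpec:
    """Planted feature table: informative columns share a latent factor (so
    each can correlate strongly with the target, as collinear vegetation
    indices do on real plots), noise columns are independent."""

    n_plots: int = 200
    n_informative: int = 4
    n_noise: int = 26
    coefficients: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    informative_correlation: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        total = self.n_informative + self.n_noise
        if self.n_plots <= total:
            raise FieldSpecError(
                f"n_plots ({self.n_plots}) must exceed the total feature count "
                f"({total}) for identifiable recovery")
        if self.noise_sd < 0:
            raise FieldSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.informative_correlation < 1.0:
            raise FieldSpecError(
                "informative_correlation must be in [0, 1), got "
                f"{self.informative_correlation}")
        if self.coefficients is not None and len(self.coefficients) != self.n_informative:
            raise FieldSpecError(
                f"coefficients must have length n_informative={self.n_informative}")


_INFORMATIVE_NAME_POOL = ("B", "a", "ExR", "H", "ExG", "COM", "NGRDI", "NDRE")


@dataclass
class FeatureTable:
    features: "pd.DataFrame"       # noqa: F821 - standardized columns
    target: np.ndarray             # coverage-like response
    informative: list[str]


def generate_feature_table(spec: SyntheticFeatureSpec) -> FeatureTable:
    """Standardized feature matrix + target with a planted linear signal."""
    import pandas as pd

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k, m = spec.n_plots, spec.n_informative, spec.n_noise
    rho = spec.informative_correlation
    coefs = (np.asarray(spec.coefficients, dtype=float)
             if spec.coefficients is not None else np.ones(k))

    latent = rng.standard_normal(n)
    informative = (np.sqrt(rho) * latent[:, None]
                   + np.sqrt(1 - rho) * rng.standard_normal((n, k)))
    noise_cols = rng.standard_normal((n, m))
    target = informative @ coefs + spec.noise_sd * rng.standard_normal(n)

    X = np.concatenate([informative, noise_cols], axis=1)
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    if k <= len(_INFORMATIVE_NAME_POOL):
        inf_names = list(_INFORMATIVE_NAME_POOL[:k])
    else:
        inf_names = [f"inf_{i:02d}" for i in range(k)]
    names = inf_names + [f"noise_{i:02d}" for i in range(m)]
    frame = pd.DataFrame(X, columns=names)
    return FeatureTable(features=frame, target=target, informative=inf_names)
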