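"""Canopy coverage from segmentation masks and its correlation with traits.

Canopy coverage = plant pixels / total pixels, an exact integer ratio.
Multiple strips of one variety are pooled at the pixel level (sum the
counts, then divide), which is well-defined for unequal strip sizes and
always lies between the per-strip extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CoverageRecord",
    "canopy_coverage",
    "coverage_by_variety",
    "correlate_coverage_yield",
]


@dataclass
class CoverageRecord:
    plot_id: str
    variety: str
    plant_pixels: int
    total_pixels: int

    @property
    def coverage(self) -> float:
        return self.plant_pixels / self.total_pixels

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.plant_pixels / self.total_pixels


def canopy_coverage(mask: np.ndarray, plot_id: str = "",
                    variety: str = "") -> CoverageRecord:
    """Exact plant-pixel fraction of a {0, 1} class map."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask is empty")
    values = set(np.unique(mask).tolist())
    if values - {0, 1}:
        raise ValueError(
            f"mask must be a {{0, 1}} class map, found values {sorted(values)}")
    plant = int((mask == 1).sum())
    return CoverageRecord(plot_id=plot_id, variety=variety,
                          plant_pixels=plant, total_pixels=int(mask.size))


def coverage_by_variety(masks: list[np.ndarray], plot_ids: list[str],
                        varieties: list[str]) -> pd.DataFrame:
    """One pooled CoverageRecord per variety.

    Strips sharing a variety are pixel-pooled; duplicate plot_ids are
    rejected. Returns a DataFrame indexed by variety with plant_pixels,
    total_pixels, coverage and coverage_percent columns.
    """
    if not (len(masks) == len(plot_ids) == len(varieties)):
        raise ValueError("masks, plot_ids and varieties must have equal length")
    if len(set(plot_ids)) != len(plot_ids):
        dupes = sorted({p for p in plot_ids if plot_ids.count(p) > 1})
        raise ValueError(f"duplicate plot_id(s): {dupes}")
    pooled: dict[str, list[int]] = {}
    for mask, pid, variety in zip(masks, plot_ids, varieties):
        rec = canopy_coverage(mask, plot_id=pid, variety=variety)
        agg = pooled.setdefault(variety, [0, 0])
        agg[0] += rec.plant_pixels
        agg[1] += rec.total_pixels
    rows = []
    for variety, (plant, total) in pooled.items():
        rows.append({"variety": variety, "plant_pixels": plant,
                     "total_pixels": total, "coverage": plant / total,
                     "coverage_percent": 100.0 * plant / total})
    return pd.DataFrame(rows).set_index("variety")


def correlate_coverage_yield(coverage: pd.DataFrame,
                             traits: pd.DataFrame,
                             trait_column: str = "dry_bark_yield"
                             ) -> dict:
    """Pearson r between per-variety coverage and a trait column.

    Both frames must be indexed by variety; only shared varieties enter the
    correlation. Returns r, the two-sided p-value, n and the paired data.
    """
    shared = coverage.index.intersection(traits.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared varieties, found {len(shared)}")
    x = coverage.loc[shared, "coverage"].to_numpy(dtype=float)
    y = traits.loc[shared, trait_column].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in coverage or trait values")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": int(len(shared)),
            "pairs": pd.DataFrame({"coverage": x, trait_column: y},
                                  index=shared)}
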