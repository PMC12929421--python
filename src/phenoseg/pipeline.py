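"""Experiment orchestration at desk scale: model comparison, optimizer/SE
and augmentation ablations, and the segmentation → coverage → features →
selection analysis chain.

Two profiles are shipped: ``desk`` (small channel widths and a few hundred
iterations on synthetic tiles — the scale used by the test suite and the
reproduction script) and ``paper`` (the full reference protocol: 40 000
iterations, validation every 4 000, base width 64). Every report embeds the
resolved configuration and seeds, so any table can be regenerated from its
report file. Wall-clock columns are informational only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasetio import AugmentationConfig, SplitManifest, split_dataset
from .inference import Segmenter, TTAConfig, WindowConfig, predict_sliding
from .features import extract_features
from .metrics import compute_metrics, confusion
from .models import SegModelConfig, build_model
from .selection import (SelectionConfig, cars_select, consensus, lars_select,
                        lasso_select, pearson_screen)
from .coverage import canopy_coverage, correlate_coverage_yield
from .synthfield import FieldSpec, TilePair, generate_tile
from .training import TrainConfig, train

logger = logging.getLogger(__name__)

__all__ = [
    "PROFILES",
    "RunSpec",
    "ExperimentPlan",
    "AblationPlan",
    "make_synthetic_dataset",
    "run_model_comparison",
    "run_ablation",
    "run_phenotyping_chain",
]

PROFILES = {
    "desk": {
        "base_channels": 16,
        "max_iters": 300,
        "val_interval": 100,
        "batch_size": 8,
        "n_tiles": 300,
        "tile_size": 128,
    },
    "paper": {
        "base_channels": 64,
        "max_iters": 40_000,
        "val_interval": 4_000,
        "batch_size": 8,
        "n_tiles": 600,
        "tile_size": 512,
    },
}


@dataclass
class RunSpec:
    name: str
    model: SegModelConfig
    train: TrainConfig
    augmentation: AugmentationConfig

    def resolved(self) -> dict:
        return {"name": self.name,
                "model": self.model.to_dict(),
                "train": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                          for k, v in asdict(self.train).items()},
                "augmentation": asdict(self.augmentation)}


@dataclass
class ExperimentPlan:
    name: str
    runs: list[RunSpec]
    evaluation_split: str = "test"
    seed: int = 0

    def __post_init__(self) -> None:
        names = [r.name for r in self.runs]
        if len(set(names)) != len(names):
            raise ValueError(f"run names must be unique, got {names}")
        if self.evaluation_split not in ("val", "test"):
            raise ValueError("evaluation_split must be 'val' or 'test'")


@dataclass
class AblationPlan:
    """One training run per single-enabled augmentation strategy."""

    base: RunSpec
    strategies: tuple[str, ...] = ("scale", "flip", "photometric")

    def expand(self) -> list[RunSpec]:
        runs = []
        for strategy in self.strategies:
            aug = self.base.augmentation.with_only(strategy)
            if len(aug.enabled_strategies) != 1:
                raise ValueError(
                    f"ablation run must enable exactly one strategy, got "
                    f"{aug.enabled_strategies}")
            runs.append(RunSpec(name=strategy, model=self.base.model,
                                train=self.base.train, augmentation=aug))
        return runs


def make_synthetic_dataset(n_tiles: int = 300, tile_size: int = 128,
                           seed: int = 0, ratio=(8, 1, 1),
                           field_spec: FieldSpec | None = None
                           ) -> tuple[dict[str, TilePair], SplitManifest]:
    """Seeded tile collection + 8:1:1 split manifest.

    Tile i is generated from an independent seed derived from ``seed`` so
    the collection is reproducible and individual tiles are independent.
    """
    base = field_spec or FieldSpec()
    tiles: dict[str, TilePair] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_tiles)
    for i in range(n_tiles):
        spec = FieldSpec(**{**asdict(base),
                            "tile_height": tile_size,
                            "tile_width": tile_size,
                            "seed": int(child_seeds[i] % (2 ** 31))})
        pid = f"tile_{i:04d}"
        tiles[pid] = generate_tile(spec, plot_id=pid)
    manifest = split_dataset(sorted(tiles), ratio=ratio, seed=seed)
    return tiles, manifest


def _run_one(run: RunSpec, tiles: dict[str, TilePair],
             manifest: SplitManifest, eval_split: str) -> dict:
    t0 = time.perf_counter()
    train_tiles = [tiles[i] for i in manifest.train]
    val_tiles = [tiles[i] for i in manifest.val]
    eval_tiles = [tiles[i] for i in
                  (manifest.test if eval_split == "test" else manifest.val)]
    data_time = time.perf_counter() - t0

    model = build_model(run.model, seed=run.train.seed)
    result = train(model, train_tiles, val_tiles, run.train,
                   aug=run.augmentation)
    best_model = result.best.build_model()

    t1 = time.perf_counter()
    preds, truths = [], []
    from .datasetio import encode_label, normalize
    for tile in eval_tiles:
        x = normalize(tile.image, result.stats).transpose(2, 0, 1)[None]
        preds.append(best_model.predict_logits(x)[0].argmax(axis=0).astype(np.uint8))
        truths.append(encode_label(tile.mask))
    infer_time = time.perf_counter() - t1

    report = compute_metrics(confusion(np.stack(preds).ravel(),
                                       np.stack(truths).ravel()))
    return {
        "name": run.name,
        "config": run.resolved(),
        "metrics": report.as_percent_table(),
        "macro_iou": report.macro.iou,
        "best_val_iou": result.best.best_val_iou,
        "history": result.history,
        "data_loading_time_s": round(data_time, 3),
        "model_run_time_s": round(infer_time, 3),
    }


def run_model_comparison(plan: ExperimentPlan, tiles: dict[str, TilePair],
                         manifest: SplitManifest,
                         out_dir: str | Path | None = None) -> dict:
    """Train every run under its config and evaluate on the shared split.

    A failing run is recorded in the report instead of aborting the whole
    comparison.
    """
    report: dict = {"plan": plan.name, "seed": plan.seed,
                    "evaluation_split": plan.evaluation_split,
                    "split": {"train": len(manifest.train),
                              "val": len(manifest.val),
                              "test": len(manifest.test),
                              "seed": manifest.seed},
                    "runs": [], "failures": []}
    for run in plan.runs:
        logger.info("comparison run %s", run.name)
        try:
            report["runs"].append(
                _run_one(run, tiles, manifest, plan.evaluation_split))
        except Exception as exc:   # partial report with failure recorded
            logger.exception("run %s failed", run.name)
            report["failures"].append({"name": run.name, "error": repr(exc)})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{plan.name}_report.json").write_text(
            json.dumps(report, indent=1, default=float))
        _metrics_csv(report, out / f"{plan.name}_metrics.csv")
    return report


def _metrics_csv(report: dict, path: Path) -> None:
    rows = []
    for run in report["runs"]:
        for row in run["metrics"]:
            rows.append({"model": run["name"], "type": row["class"],
                         **{k: v for k, v in row.items() if k != "class"},
                         "data_loading_time": run["data_loading_time_s"],
                         "model_run_time": run["model_run_time_s"]})
    pd.DataFrame(rows).to_csv(path, index=False)


def run_ablation(plan: AblationPlan, tiles: dict[str, TilePair],
                 manifest: SplitManifest,
                 eval_tiles: dict[str, TilePair] | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """One training run per single-enabled strategy (ablation layout).

    ``eval_tiles`` optionally replaces the test split, e.g. with an
    illumination-shifted benchmark probing photometric robustness.
    """
    runs = plan.expand()
    exp = ExperimentPlan(name="augmentation_ablation", runs=runs,
                         seed=plan.base.train.seed)
    if eval_tiles is not None:
        tiles = {**tiles, **eval_tiles}
        manifest = SplitManifest(train=manifest.train, val=manifest.val,
                                 test=sorted(eval_tiles), ratio=manifest.ratio,
                                 seed=manifest.seed)
    return run_model_comparison(exp, tiles, manifest, out_dir=out_dir)


def run_phenotyping_chain(segmenter: Segmenter | None,
                          strips: list[TilePair],
                          metadata: pd.DataFrame,
                          traits: pd.DataFrame | None = None,
                          *,
                          window: WindowConfig | None = None,
                          tta: TTAConfig | None = None,
                          selection_config: SelectionConfig | None = None,
                          use_oracle_masks: bool = False,
                          out_dir: str | Path | None = None) -> dict:
    """Segment strips, derive per-variety coverage, extract features over
    the predicted masks, run four-method selection and consensus.

    With ``use_oracle_masks=True`` the ground-truth masks bypass the model
    (a pass-through mode for validating the downstream chain in isolation).
    ``metadata`` must carry plot_id and variety columns covering every strip.
    """
    meta = metadata.set_index("plot_id")
    missing = [s.plot_id for s in strips if s.plot_id not in meta.index]
    if missing:
        raise ValueError(f"metadata is missing plot_ids: {missing}")

    masks, records, feature_rows = [], [], []
    for strip in strips:
        if use_oracle_masks or segmenter is None:
            class_map = (strip.mask == 255).astype(np.uint8)
        else:
            class_map = predict_sliding(segmenter, strip.image,
                                        window=window, tta=tta)
        masks.append(class_map)
        variety = str(meta.loc[strip.plot_id, "variety"])
        rec = canopy_coverage(class_map, plot_id=strip.plot_id, variety=variety)
        records.append(rec)
        fv = extract_features(strip.image, class_map)
        feature_rows.append({"plot_id": strip.plot_id, "variety": variety,
                             **fv.values})

    coverage_df = pd.DataFrame(
        [{"plot_id": r.plot_id, "variety": r.variety,
          "plant_pixels": r.plant_pixels, "total_pixels": r.total_pixels,
          "coverage": r.coverage, "coverage_percent": r.coverage_percent}
         for r in records])
    features_df = pd.DataFrame(feature_rows)

    sel_cfg = selection_config or SelectionConfig()
    X = features_df.drop(columns=["plot_id", "variety"])
    X = X.loc[:, X.notna().all()]
    y = coverage_df["coverage"].to_numpy()
    screen = pearson_screen(X, y, sel_cfg.pearson_threshold)
    if sel_cfg.lars_max_steps is not None:
        k = sel_cfg.lars_max_steps
    elif screen.selected:
        k = len(screen.selected)   # LARS output sized like the screen
    else:
        k = min(4, X.shape[1])
    results = [screen,
               lasso_select(X, y, sel_cfg),
               lars_select(X, y, k=min(k, X.shape[1])),
               cars_select(X, y, sel_cfg)]
    cons = consensus(results)

    bundle = {
        "coverage": coverage_df,
        "features": features_df,
        "selection": {r.method: r for r in results},
        "consensus": cons,
        "provenance": {
            "n_strips": len(strips),
            "use_oracle_masks": bool(use_oracle_masks or segmenter is None),
            "window": asdict(window) if window else None,
            "tta": asdict(tta) if tta else None,
            "selection_seed": sel_cfg.seed,
        },
    }
    if traits is not None:
        cov_by_var = coverage_df.groupby("variety")[["coverage"]].mean()
        try:
            bundle["yield_correlation"] = correlate_coverage_yield(
                cov_by_var, traits)
        except ValueError as exc:
            bundle["yield_correlation"] = {"error": str(exc)}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        coverage_df.to_csv(out / "coverage.csv", index=False)
        features_df.to_csv(out / "features.csv", index=False)
        cons["table"].to_csv(out / "consensus.csv", index=False)
        (out / "selection.json").write_text(json.dumps(
            {r.method: r.selected for r in results}, indent=1))
    return bundle
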