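"""Unified training harness: optimizer presets, polynomial LR decay,
iteration-based loop with periodic validation, checkpointing and resume.

The two optimizer presets are SGD (lr 0.0025, momentum 0.9, weight decay
5e-4, LR floor 1e-4) and AdamW (lr 1e-4, betas 0.9/0.999, decoupled decay
0.01, LR floor 1e-6), both under polynomial decay
``lr(t) = (base - min) * (1 - t/T)^power + min`` with power 0.9. Model
selection uses validation macro IoU, the headline segmentation metric.
The reference protocol runs 40 000 iterations with validation every 4 000;
desk-scale experiments shrink both while keeping every other setting.
"""

from __future__ import annotations

import csv

import logging
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .datasetio import (AugmentationConfig, NormalizationStats, compute_stats,
                        encode_label, normalize, random_augment)
from .models import SegModelConfig, SegmentationModel, build_model
from .synthfield import TilePair

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerSpec",
    "ScheduleSpec",
    "TrainConfig",
    "poly_lr",
    "train",
    "resume",
    "TrainResult",
    "Checkpoint",
    "evaluate_tiles",
    "evaluate_tiles_report",
]


@dataclass
class OptimizerSpec:
    kind: str = "adamw"
    learning_rate: float = 1e-4
    momentum: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("sgd", "adamw"):
            raise ValueError(f"optimizer kind must be 'sgd' or 'adamw', got {self.kind!r}")

    @classmethod
    def sgd_preset(cls) -> "OptimizerSpec":
        return cls(kind="sgd", learning_rate=0.0025, momentum=0.9,
                   weight_decay=0.0005)

    @classmethod
    def adamw_preset(cls) -> "OptimizerSpec":
        return cls(kind="adamw", learning_rate=0.0001, beta1=0.9, beta2=0.999,
                   weight_decay=0.01)

    def default_min_lr(self) -> float:
        return 1e-4 if self.kind == "sgd" else 1e-6

    def build(self, params: list[nn.Parameter], lr: float):
        if self.kind == "sgd":
            return nn.SGD(params, lr, momentum=self.momentum,
                          weight_decay=self.weight_decay)
        return nn.AdamW(params, lr, betas=(self.beta1, self.beta2),
                        weight_decay=self.weight_decay)


@dataclass
class ScheduleSpec:
    kind: str = "poly"
    base_lr: float = 1e-4
    min_lr: float = 1e-6
    power: float = 0.9
    max_iters: int = 40_000

    def __post_init__(self) -> None:
        if self.kind != "poly":
            raise ValueError("only the 'poly' schedule is implemented")
        if not 0 < self.min_lr < self.base_lr:
            raise ValueError(
                f"need 0 < min_lr < base_lr, got min_lr={self.min_lr}, "
                f"base_lr={self.base_lr}")

    @classmethod
    def for_optimizer(cls, opt: OptimizerSpec, max_iters: int) -> "ScheduleSpec":
        return cls(base_lr=opt.learning_rate, min_lr=opt.default_min_lr(),
                   max_iters=max_iters)


def poly_lr(iteration: int, schedule: ScheduleSpec) -> float:
    """lr = (base - min) * (1 - t/T)^power + min, clamped past T."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if iteration > schedule.max_iters:
        warnings.warn(f"iteration {iteration} beyond max_iters "
                      f"{schedule.max_iters}; clamping to min_lr")
        return schedule.min_lr
    frac = 1.0 - iteration / schedule.max_iters
    return (schedule.base_lr - schedule.min_lr) * frac ** schedule.power \
        + schedule.min_lr


@dataclass
class TrainConfig:
    max_iters: int = 40_000
    val_interval: int = 4_000
    batch_size: int = 8
    seed: int = 0
    optimizer: OptimizerSpec = field(default_factory=OptimizerSpec.adamw_preset)
    schedule: ScheduleSpec | None = None
    checkpoint_dir: str | None = None
    resume: bool = False
    crop_size: tuple[int, int] | None = None   # default: native tile size

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_iters > 0 and self.val_interval > self.max_iters:
            raise ValueError("val_interval must be <= max_iters")
        if self.schedule is None:
            self.schedule = ScheduleSpec.for_optimizer(
                self.optimizer, max(self.max_iters, 1))


@dataclass
class Checkpoint:
    model_config: SegModelConfig
    arrays: list[np.ndarray]
    iteration: int
    best_val_iou: float
    stats: NormalizationStats
    optimizer_state: dict | None = None
    rng_state: dict | None = None
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump({
                "model_config": self.model_config.to_dict(),
                "arrays": self.arrays,
                "iteration": self.iteration,
                "best_val_iou": self.best_val_iou,
                "stats": {"mean": self.stats.mean, "std": self.stats.std},
                "optimizer_state": self.optimizer_state,
                "rng_state": self.rng_state,
                "history": self.history,
            }, fh)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with open(Path(path), "rb") as fh:
            d = pickle.load(fh)
        return cls(model_config=SegModelConfig.from_dict(d["model_config"]),
                   arrays=d["arrays"], iteration=d["iteration"],
                   best_val_iou=d["best_val_iou"],
                   stats=NormalizationStats(mean=tuple(d["stats"]["mean"]),
                                            std=tuple(d["stats"]["std"])),
                   optimizer_state=d["optimizer_state"],
                   rng_state=d["rng_state"], history=d["history"])

    def build_model(self) -> SegmentationModel:
        model = build_model(self.model_config, seed=0)
        model.load_state_arrays(self.arrays)
        return model


@dataclass
class TrainResult:
    model: SegmentationModel
    best: Checkpoint
    history: list[dict]
    stats: NormalizationStats

    def history_to_csv(self, path: str | Path) -> None:
        if not self.history:
            Path(path).write_text("")
            return
        keys = list(dict.fromkeys(k for rec in self.history for k in rec))
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys, restval="")
            writer.writeheader()
            writer.writerows(self.history)


def _batch_to_arrays(pairs: list[TilePair], stats: NormalizationStats
                     ) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([normalize(p.image, stats).transpose(2, 0, 1)
                       for p in pairs])
    labels = np.stack([encode_label(p.mask).astype(np.int64) for p in pairs])
    return images, labels


def evaluate_tiles_report(model: SegmentationModel, tiles: list[TilePair],
                          stats: NormalizationStats, batch_size: int = 8):
    """Full metric report of direct (no TTA) predictions pooled over tiles."""
    from .metrics import compute_metrics, confusion

    preds, truths = [], []
    for i in range(0, len(tiles), batch_size):
        chunk = tiles[i:i + batch_size]
        x, y = _batch_to_arrays(chunk, stats)
        logits = model.predict_logits(x)
        preds.append(logits.argmax(axis=1).astype(np.uint8))
        truths.append(y.astype(np.uint8))
    return compute_metrics(confusion(np.concatenate(preds).ravel(),
                                     np.concatenate(truths).ravel()))


def evaluate_tiles(model: SegmentationModel, tiles: list[TilePair],
                   stats: NormalizationStats, batch_size: int = 8) -> float:
    """Macro IoU of direct (no TTA) predictions pooled over ``tiles``."""
    return evaluate_tiles_report(model, tiles, stats, batch_size).macro.iou


def _training_loop(model: SegmentationModel, train_tiles: list[TilePair],
                   val_tiles: list[TilePair], config: TrainConfig,
                   aug: AugmentationConfig, stats: NormalizationStats,
                   optimizer, rng: np.random.Generator, start_iter: int,
                   history: list[dict], best: Checkpoint | None
                   ) -> tuple[Checkpoint, list[dict]]:
    crop = config.crop_size or train_tiles[0].mask.shape
    n_train = len(train_tiles)

    def make_checkpoint(iteration: int, best_iou: float) -> Checkpoint:
        return Checkpoint(
            model_config=model.config,
            arrays=[a.copy() for a in model.state_arrays()],
            iteration=iteration, best_val_iou=best_iou, stats=stats,
            optimizer_state=optimizer.state(),
            rng_state=rng.bit_generator.state,
            history=list(history))

    best_iou = best.best_val_iou if best is not None else -np.inf

    for it in range(start_iter, config.max_iters):
        lr = poly_lr(it, config.schedule)
        optimizer.lr = lr
        idx = rng.integers(0, n_train, size=config.batch_size)
        batch = [random_augment(train_tiles[int(i)], aug, rng, crop_size=crop)
                 for i in idx]
        x, y = _batch_to_arrays(batch, stats)
        model.train()
        logits = model.forward(x)
        loss, dlogits = nn.softmax_cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss} at iteration {it}; aborting "
                f"(lr={lr:.3g}, batch indices={idx.tolist()})")
        model.zero_grad()
        model.backward(dlogits)
        optimizer.step()

        record = {"iter": it + 1, "loss": loss, "lr": lr}
        is_val = ((it + 1) % config.val_interval == 0
                  or (it + 1) == config.max_iters)
        if is_val:
            val_report = evaluate_tiles_report(model, val_tiles, stats,
                                               config.batch_size)
            val_iou = val_report.macro.iou
            record["val_macro_iou"] = val_iou
            record["val_plant_iou"] = val_report.per_class["plant"].iou
            record["val_background_iou"] = \
                val_report.per_class["background"].iou
            logger.info("iter %d loss %.4f lr %.3g val mIoU %.4f",
                        it + 1, loss, lr, val_iou)
            if val_iou > best_iou:
                best_iou = val_iou
                best = make_checkpoint(it + 1, best_iou)
                if config.checkpoint_dir:
                    best.save(Path(config.checkpoint_dir) / "best.ckpt")
        history.append(record)
        if config.checkpoint_dir and is_val:
            make_checkpoint(it + 1, best_iou).save(
                Path(config.checkpoint_dir) / "last.ckpt")

    if best is None:   # max_iters == 0 or no validation improvement recorded
        best = make_checkpoint(start_iter, best_iou)
    best.history = list(history)
    return best, history


def train(model: SegmentationModel, train_tiles: list[TilePair],
          val_tiles: list[TilePair], config: TrainConfig,
          aug: AugmentationConfig | None = None,
          stats: NormalizationStats | None = None) -> TrainResult:
    """Iteration-based training with periodic validation.

    Batches are drawn with replacement from ``train_tiles`` and augmented
    according to ``aug``; every ``val_interval`` steps the model is scored
    by macro IoU on ``val_tiles`` and the best checkpoint kept. All
    randomness (batch order, augmentation draws) derives from
    ``config.seed``.
    """
    if not train_tiles or not val_tiles:
        raise ValueError("train and val splits must be non-empty")
    aug = aug or AugmentationConfig(enabled_strategies=())
    stats = stats or compute_stats([p.image for p in train_tiles])
    rng = np.random.default_rng(config.seed)
    optimizer = config.optimizer.build(model.parameters(),
                                       config.schedule.base_lr)

    if config.max_iters == 0:
        best = Checkpoint(model_config=model.config,
                          arrays=[a.copy() for a in model.state_arrays()],
                          iteration=0, best_val_iou=float("nan"), stats=stats,
                          optimizer_state=optimizer.state(),
                          rng_state=rng.bit_generator.state, history=[])
        return TrainResult(model=model, best=best, history=[], stats=stats)

    best, history = _training_loop(model, train_tiles, val_tiles, config, aug,
                                   stats, optimizer, rng, 0, [], None)
    return TrainResult(model=model, best=best, history=history, stats=stats)


def resume(checkpoint: Checkpoint, train_tiles: list[TilePair],
           val_tiles: list[TilePair], config: TrainConfig,
           aug: AugmentationConfig | None = None,
           model: SegmentationModel | None = None) -> TrainResult:
    """Continue training from a checkpoint up to ``config.max_iters``.

    The LR schedule is evaluated at the *global* iteration counter, and the
    optimizer moments and RNG state are restored, so an interrupted-and-
    resumed run retraces the uninterrupted one.
    """
    if model is None:
        model = checkpoint.build_model()
    elif model.config != checkpoint.model_config:
        diffs = [f for f in vars(model.config)
                 if getattr(model.config, f) != getattr(checkpoint.model_config, f)]
        raise ValueError(
            f"checkpoint architecture mismatch in fields: {diffs}")
    else:
        model.load_state_arrays(checkpoint.arrays)
    aug = aug or AugmentationConfig(enabled_strategies=())
    stats = checkpoint.stats
    rng = np.random.default_rng(config.seed)
    if checkpoint.rng_state is not None:
        rng.bit_generator.state = checkpoint.rng_state
    optimizer = config.optimizer.build(model.parameters(),
                                       config.schedule.base_lr)
    if checkpoint.optimizer_state is not None:
        optimizer.load_state(checkpoint.optimizer_state)

    history = list(checkpoint.history)
    best, history = _training_loop(model, train_tiles, val_tiles, config, aug,
                                   stats, optimizer, rng,
                                   checkpoint.iteration, history, checkpoint)
    return TrainResult(model=model, best=best, history=history, stats=stats)
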