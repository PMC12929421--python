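"""YAML experiment configuration.

Config files mirror the dataclass field names, e.g.::

    model:
      arch: se_unet
      base_channels: 16
    optimizer:
      kind: adamw
    schedule:
      base_lr: 0.0001
      min_lr: 1.0e-6
    max_iters: 300
    val_interval: 100
    augmentation:
      enabled_strategies: [scale, flip, photometric]
      crop_size: [512, 512]
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .datasetio import AugmentationConfig
from .models import SegModelConfig
from .training import OptimizerSpec, ScheduleSpec, TrainConfig

__all__ = ["load_experiment_config", "save_experiment_config"]

_TUPLE_FIELDS = {"scale_levels", "crop_size", "flip_axes",
                 "enabled_strategies", "aspp_dilations"}


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
            for k, v in d.items()}


def load_experiment_config(path: str | Path) -> dict:
    """Read a YAML experiment file into config dataclasses.

    Returns a dict with ``model`` (SegModelConfig), ``train`` (TrainConfig)
    and ``augmentation`` (AugmentationConfig) entries; unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"model", "optimizer", "schedule", "augmentation", "max_iters",
             "val_interval", "batch_size", "seed", "checkpoint_dir", "resume"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    model = SegModelConfig.from_dict(_tuplify(raw.get("model", {})))
    optimizer = OptimizerSpec(**raw.get("optimizer", {})) \
        if "optimizer" in raw else OptimizerSpec.adamw_preset()
    schedule = ScheduleSpec(**raw["schedule"]) if "schedule" in raw else None
    train = TrainConfig(
        max_iters=raw.get("max_iters", 40_000),
        val_interval=raw.get("val_interval", 4_000),
        batch_size=raw.get("batch_size", 8),
        seed=raw.get("seed", 0),
        optimizer=optimizer,
        schedule=schedule,
        checkpoint_dir=raw.get("checkpoint_dir"),
        resume=raw.get("resume", False))
    augmentation = AugmentationConfig(**_tuplify(raw.get("augmentation", {})))
    return {"model": model, "train": train, "augmentation": augmentation}


def save_experiment_config(path: str | Path, *, model: SegModelConfig,
                           train: TrainConfig,
                           augmentation: AugmentationConfig) -> None:
    """Write the inverse of :func:`load_experiment_config`."""
    payload = {
        "model": model.to_dict(),
        "optimizer": asdict(train.optimizer),
        "schedule": asdict(train.schedule),
        "max_iters": train.max_iters,
        "val_interval": train.val_interval,
        "batch_size": train.batch_size,
        "seed": train.seed,
        "augmentation": {k: list(v) if isinstance(v, tuple) else v
                         for k, v in asdict(augmentation).items()},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
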