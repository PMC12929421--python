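"""Schedule, optimizer presets, the training loop and checkpoint resume."""

import numpy as np
import pytest

from phenoseg.models import SegModelConfig, build_model
from phenoseg.training import (Checkpoint, OptimizerSpec, ScheduleSpec,
                               TrainConfig, poly_lr, resume, train)


def small_train_setup(tiny_dataset, max_iters=10, seed=0, arch="unet",
                      base_channels=4):
    cfg = TrainConfig(max_iters=max_iters, val_interval=max(1, max_iters // 2),
                      batch_size=2, seed=seed,
                      optimizer=OptimizerSpec.adamw_preset())
    model = build_model(SegModelConfig(arch=arch, base_channels=base_channels,
                                       encoder_stages=3), seed=seed)
    train_t, val_t = tiny_dataset[:24], tiny_dataset[24:28]
    return model, train_t, val_t, cfg


class TestPolyLR:
    def test_endpoints(self):
        sched = ScheduleSpec(base_lr=0.01, min_lr=1e-4, power=0.9,
                             max_iters=100)
        assert poly_lr(0, sched) == 0.01
        assert poly_lr(100, sched) == pytest.approx(1e-4, abs=0)

    def test_linear_midpoint(self):
        sched = ScheduleSpec(base_lr=0.01, min_lr=0.002, power=1.0,
                             max_iters=100)
        assert poly_lr(50, sched) == pytest.approx((0.01 + 0.002) / 2)

    def test_monotone_nonincreasing_and_bounded(self):
        sched = ScheduleSpec(base_lr=0.0025, min_lr=1e-4, power=0.9,
                             max_iters=200)
        lrs = [poly_lr(i, sched) for i in range(201)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert min(lrs) >= 1e-4 and max(lrs) <= 0.0025

    def test_beyond_max_iters_clamps_with_warning(self):
        sched = ScheduleSpec(base_lr=0.01, min_lr=1e-4, max_iters=10)
        with pytest.warns(UserWarning, match="clamp"):
            assert poly_lr(11, sched) == 1e-4


class TestPresets:
    def test_sgd_preset_values(self):
        opt = OptimizerSpec.sgd_preset()
        assert (opt.learning_rate, opt.momentum, opt.weight_decay) == \
            (0.0025, 0.9, 0.0005)
        assert opt.default_min_lr() == 1e-4

    def test_adamw_preset_values(self):
        opt = OptimizerSpec.adamw_preset()
        assert (opt.learning_rate, opt.beta1, opt.beta2, opt.weight_decay) == \
            (0.0001, 0.9, 0.999, 0.01)
        assert opt.default_min_lr() == 1e-6

    def test_reference_protocol_defaults(self):
        cfg = TrainConfig()
        assert cfg.max_iters == 40_000
        assert cfg.val_interval == 4_000
        assert cfg.schedule.max_iters == 40_000


class TestTrainLoop:
    def test_zero_iterations_returns_initial_weights(self, tiny_dataset):
        model, train_t, val_t, cfg = small_train_setup(tiny_dataset,
                                                       max_iters=0)
        before = [a.copy() for a in model.state_arrays()]
        result = train(model, train_t, val_t, cfg)
        assert result.history == []
        for a, b in zip(before, result.model.state_arrays()):
            assert np.array_equal(a, b)

    def test_seed_determinism_identical_loss_trajectories(self, tiny_dataset):
        losses = []
        for _ in range(2):
            model, train_t, val_t, cfg = small_train_setup(tiny_dataset,
                                                           max_iters=6, seed=4)
            result = train(model, train_t, val_t, cfg)
            losses.append([h["loss"] for h in result.history])
        assert losses[0] == losses[1]

    def test_empty_split_rejected(self, tiny_dataset):
        model, train_t, _, cfg = small_train_setup(tiny_dataset)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, train_t, [], cfg)

    def test_best_checkpoint_iou_equals_history_max(self, tiny_dataset):
        model, train_t, val_t, cfg = small_train_setup(tiny_dataset,
                                                       max_iters=8)
        result = train(model, train_t, val_t, cfg)
        vals = [h["val_macro_iou"] for h in result.history
                if "val_macro_iou" in h]
        assert result.best.best_val_iou == max(vals)

    def test_history_records_iter_loss_lr(self, tiny_dataset):
        model, train_t, val_t, cfg = small_train_setup(tiny_dataset,
                                                       max_iters=4)
        result = train(model, train_t, val_t, cfg)
        assert len(result.history) == 4
        for rec in result.history:
            assert {"iter", "loss", "lr"} <= set(rec)


class TestResume:
    def test_schedule_uses_global_iteration_counter(self, tiny_dataset):
        model, train_t, val_t, cfg = small_train_setup(tiny_dataset,
                                                       max_iters=6, seed=1)
        first = train(model, train_t, val_t, cfg)
        last_ckpt = Checkpoint(model_config=model.config,
                               arrays=[a.copy() for a in model.state_arrays()],
                               iteration=6, best_val_iou=0.0,
                               stats=first.stats,
                               optimizer_state=None, rng_state=None,
                               history=first.history)
        cfg2 = TrainConfig(max_iters=12, val_interval=6, batch_size=2, seed=1,
                           optimizer=OptimizerSpec.adamw_preset(),
                           schedule=ScheduleSpec(base_lr=1e-4, min_lr=1e-6,
                                                 max_iters=12))
        cont = resume(last_ckpt, train_t, val_t, cfg2)
        lrs = {h["iter"]: h["lr"] for h in cont.history}
        assert lrs[9] == pytest.approx(poly_lr(8, cfg2.schedule))

    def test_architecture_mismatch_names_fields(self, tiny_dataset):
        model, train_t, val_t, cfg = small_train_setup(tiny_dataset,
                                                       max_iters=2)
        result = train(model, train_t, val_t, cfg)
        other = build_model(SegModelConfig(arch="unet", base_channels=4,
                                           encoder_stages=3, num_classes=3),
                            seed=0)
        with pytest.raises(ValueError, match="num_classes"):
            resume(result.best, train_t, val_t, cfg, model=other)

    def test_interrupted_run_retraces_uninterrupted(self, tiny_dataset):
        """With optimizer and RNG state in the checkpoint, stopping at
        iteration k and resuming reproduces the one-shot run."""
        model, train_t, val_t, cfg = small_train_setup(tiny_dataset,
                                                       max_iters=8, seed=7)
        full = train(model, train_t, val_t, cfg)

        # interrupted run: stop at iteration 4 but keep the 8-iteration
        # schedule horizon; the best checkpoint carries weights, optimizer
        # moments and the RNG state at the interruption point
        model2 = build_model(SegModelConfig(arch="unet", base_channels=4,
                                            encoder_stages=3), seed=7)
        horizon = ScheduleSpec(base_lr=1e-4, min_lr=1e-6, max_iters=8)
        cfg_a = TrainConfig(max_iters=4, val_interval=4, batch_size=2, seed=7,
                            optimizer=OptimizerSpec.adamw_preset(),
                            schedule=horizon)
        part = train(model2, train_t, val_t, cfg_a)
        assert part.best.iteration == 4
        cfg_b = TrainConfig(max_iters=8, val_interval=4, batch_size=2, seed=7,
                            optimizer=OptimizerSpec.adamw_preset())
        resumed = resume(part.best, train_t, val_t, cfg_b)
        assert abs(full.best.best_val_iou - resumed.best.best_val_iou) <= 0.05


def test_nonfinite_loss_aborts_with_diagnostic(tiny_dataset):
    model, train_t, val_t, cfg = small_train_setup(tiny_dataset, max_iters=3)
    for p in model.parameters():
        p.data[...] = np.inf
    with pytest.raises(RuntimeError, match="non-finite"):
        train(model, train_t, val_t, cfg)
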