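"""Optimization loop: Adamax, reduce-on-plateau scheduling, seeded patch
sampling, per-epoch loss breakdown history and best-checkpoint retention.

One "epoch" is a fixed, configurable number of sampled batches (the patch
pipeline is generative, so there is no finite dataset to cycle through).
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lc_patching import sample_training_patches
from .losses import LossConfig, combined_loss
from .nn import Adamax, ReduceLROnPlateau
from .noise_model import NoiseModel
from .phantoms import ChannelStack, MixTask, NoiseSpec, apply_noise
from .vse import NormStats, VSEModel, save_checkpoint


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epoch: int = 400
    learning_rate: float = 0.001
    scheduler_patience: int = 150
    scheduler_factor: float = 0.5
    min_lr: float = 1e-6
    steps_per_epoch: int = 20
    val_batches: int = 2
    seed: int = 0
    checkpoint_path: Optional[str] = None
    early_stop_patience: Optional[int] = None
    grad_clip: Optional[float] = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class FramePipeline:
    """Patch pipeline over phantom frames for one training task.

    Applies the task's noise to the clean stack once (a fixed noisy
    realization, as in a recorded acquisition), computes normalization
    statistics, and serves seeded (LC input, target) patch batches in
    normalized space together with the raw noisy targets the denoising
    branch needs.
    """

    def __init__(self, clean_stack: ChannelStack, task: MixTask,
                 patch_size: int, L: int, seed: int = 0, mode_ii_sources=None):
        self.task = task
        self.patch_size = patch_size
        self.L = 0 if task.mode == "IIb" else L
        self.clean = clean_stack
        spec = task.noise
        noisy = np.stack([
            apply_noise(clean_stack.data[c],
                        NoiseSpec(spec.gaussian_sigma, spec.poisson_scale,
                                  seed=spec.seed + 101 * (c + 1)))
            for c in range(clean_stack.k)
        ])
        self.noisy = ChannelStack(noisy, channel_names=clean_stack.channel_names,
                                  is_noisy=[True] * clean_stack.k)
        # mode II draws crops from independent per-structure source frames;
        # each gets its own fixed noisy realization
        self.mode_ii_sources = None
        if mode_ii_sources is not None:
            self.mode_ii_sources = [
                ChannelStack(
                    apply_noise(s.data,
                                NoiseSpec(spec.gaussian_sigma, spec.poisson_scale,
                                          seed=spec.seed + 307 * (i + 1))),
                    is_noisy=[True] * s.k,
                )
                for i, s in enumerate(mode_ii_sources)
            ]
        if task.mode == "III":
            w = np.asarray(task.weights, np.float32)
            acquired = apply_noise(
                np.tensordot(w, clean_stack.data, axes=(0, 0)),
                NoiseSpec(spec.gaussian_sigma, spec.poisson_scale, seed=spec.seed),
            )
            self.sample_stack = ChannelStack(
                np.concatenate([noisy, acquired[None]]),
                channel_names=clean_stack.channel_names + ["superimposed"],
                is_noisy=[True] * (clean_stack.k + 1),
            )
            self.noisy_with_input = ChannelStack(
                np.concatenate([noisy, acquired[None]]),
                is_noisy=[True] * (clean_stack.k + 1),
            )
        else:
            self.sample_stack = self.noisy
            self.noisy_with_input = None

        w = np.asarray(task.weights, np.float32)
        mixed = np.tensordot(w, noisy, axes=(0, 0))
        self.norm = NormStats(
            input_mean=float(mixed.mean()),
            input_std=float(mixed.std() + 1e-8),
            target_mean=noisy.reshape(clean_stack.k, -1).mean(axis=1).astype(np.float32),
            target_std=(noisy.reshape(clean_stack.k, -1).std(axis=1) + 1e-8).astype(np.float32),
        )

    @property
    def k(self) -> int:
        return self.clean.k

    def sample(self, n: int, seed: int):
        if self.task.mode == "II":
            stacks = self.mode_ii_sources
        else:
            stacks = self.sample_stack
        batch = sample_training_patches(
            stacks, self.task, self.patch_size, n, seed, L=self.L,
            noisy_stacks=None if self.task.mode == "II" else self.sample_stack,
        )
        raw_targets = batch.targets
        inputs = (batch.inputs - self.norm.input_mean) / self.norm.input_std
        shape = (1, self.k) + (1,) * (raw_targets.ndim - 2)
        tnorm = (raw_targets - self.norm.target_mean.reshape(shape)) / \
            self.norm.target_std.reshape(shape)
        return inputs.astype(np.float32), tnorm.astype(np.float32), raw_targets


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    lr: float
    breakdown: dict = field(default_factory=dict)


def _loss_for_batch(model, inputs, tnorm, traw, noise_model, loss_cfg, rng):
    pred, latents = model.forward(inputs, mode="sample", rng=rng)
    shapes = model.no_lc_latent_shapes(inputs.shape[2:])
    return combined_loss(
        pred, tnorm, latents, noise_model, loss_cfg, shapes,
        norm=model.norm, target_raw=traw, k_out=model.config.k_out,
        dims=model.config.dims,
    )


def _check_finite(breakdown):
    for key in ("nll_denoise", "nll_gaussian", "kl_total"):
        if not np.isfinite(breakdown[key]):
            raise RuntimeError(f"NaN/Inf loss in term '{key}'")
    for lvl, v in enumerate(breakdown["kl_per_level"]):
        if not np.isfinite(v):
            raise RuntimeError(f"NaN/Inf KL at hierarchy level {lvl}")


def train(model: VSEModel, pipeline: FramePipeline,
          noise_model: Optional[NoiseModel], loss_cfg: LossConfig,
          cfg: TrainConfig):
    """Train the model; returns (model-with-best-val-weights, history)."""
    model.norm = pipeline.norm
    opt = Adamax(model.parameters(), lr=cfg.learning_rate)
    sched = ReduceLROnPlateau(opt, factor=cfg.scheduler_factor,
                              patience=cfg.scheduler_patience, min_lr=cfg.min_lr)
    history: list[EpochRecord] = []
    best_val, best_state = np.inf, None
    bad = 0
    for epoch in range(cfg.max_epoch):
        erng = np.random.default_rng((cfg.seed, epoch))
        train_losses, bd = [], {}
        for step in range(cfg.steps_per_epoch):
            inputs, tnorm, traw = pipeline.sample(
                cfg.batch_size, seed=int(erng.integers(2**31)))
            loss, bd = _loss_for_batch(model, inputs, tnorm, traw,
                                       noise_model, loss_cfg, erng)
            _check_finite(bd)
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                for p in model.parameters():
                    if p.grad is not None:
                        np.clip(p.grad, -cfg.grad_clip, cfg.grad_clip, out=p.grad)
            opt.step()
            train_losses.append(float(loss.data))
        gc.collect()  # graphs hold large conv buffers; don't wait for gen-2
        val_loss = validate(model, pipeline, noise_model, loss_cfg, cfg)["loss"]
        lr = sched.step(val_loss)
        history.append(EpochRecord(
            epoch=epoch, train_loss=float(np.mean(train_losses)),
            val_loss=val_loss, lr=lr, breakdown=bd,
        ))
        if val_loss < best_val:
            best_val = val_loss
            best_state = [a.copy() for a in model.state_arrays()]
            bad = 0
            if cfg.checkpoint_path is not None:
                save_checkpoint(cfg.checkpoint_path, model,
                                extra={"epoch": epoch, "val_loss": val_loss})
        else:
            bad += 1
            if cfg.early_stop_patience is not None and bad > cfg.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def validate(model: VSEModel, pipeline: FramePipeline,
             noise_model: Optional[NoiseModel], loss_cfg: LossConfig,
             cfg: TrainConfig, metrics: Optional[list] = None) -> dict:
    """Loss (and optional metric callables) on held-out, val-seeded patches."""
    if cfg.val_batches < 1:
        raise ValueError("empty validation set")
    losses = []
    record: dict = {}
    for i in range(cfg.val_batches):
        vrng = np.random.default_rng((cfg.seed, 982451653, i))
        inputs, tnorm, traw = pipeline.sample(
            cfg.batch_size, seed=int(vrng.integers(2**31)))
        loss, _ = _loss_for_batch(model, inputs, tnorm, traw,
                                  noise_model, loss_cfg, vrng)
        losses.append(float(loss.data))
    record["loss"] = float(np.mean(losses))
    if metrics:
        vrng = np.random.default_rng((cfg.seed, 982451653, 2**20))
        inputs, tnorm, traw = pipeline.sample(
            cfg.batch_size, seed=int(vrng.integers(2**31)))
        pred, _ = model.forward(inputs, mode="posterior_mean")
        mean, _ = model.predict_mean_logvar(pred)
        for fn in metrics:
            record[fn.__name__] = float(fn(mean.data, tnorm))
    return record
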