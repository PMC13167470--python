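"""Hierarchical variational splitting encoder-decoder.

Bottom-up encoder over the primary patch; at each pooled hierarchy level the
pooled embedding is zero-padded back to the primary patch's spatial size and
concatenated with features from a dedicated, pooling-free input branch that
processes the matching lateral-context patch.  Merged feature maps therefore
retain the primary patch's spatial dimensions throughout the hierarchy when
LC is active.  The top-down decoder is a ladder of conditional Gaussian
latents (prior at each level conditioned on the levels above), ending in a
k-channel prediction head with optional per-pixel log-variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class ModelConfig:
    k_out: int = 2
    hierarchy_levels: int = 2
    base_filters: int = 16
    z_dim: int = 4
    L: int = 1
    variant: Literal["lean_lc", "deep_lc"] = "lean_lc"
    dims: Literal[2, 3] = 2
    predict_logvar: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.hierarchy_levels < 2:
            raise ValueError("hierarchy_levels must be >= 2")
        if self.L > self.hierarchy_levels - 1:
            raise ValueError("L must be <= hierarchy_levels - 1")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.k_out < 1 or self.base_filters < 1 or self.z_dim < 1:
            raise ValueError("k_out, base_filters, z_dim must be >= 1")

    @property
    def lc_enabled(self) -> bool:
        return self.L > 0


@dataclass
class LevelLatents:
    """Posterior and prior diagonal-Gaussian parameters at one level."""

    q_mu: Tensor
    q_logvar: Tensor
    p_mu: Tensor
    p_logvar: Tensor


@dataclass
class NormStats:
    input_mean: float = 0.0
    input_std: float = 1.0
    target_mean: np.ndarray = field(default_factory=lambda: np.zeros(1, np.float32))
    target_std: np.ndarray = field(default_factory=lambda: np.ones(1, np.float32))


def _split_mu_logvar(t: Tensor):
    c = t.shape[1] // 2
    return t[:, :c], t[:, c:]


class VSEModel(nn.Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, z, d = config.base_filters, config.z_dim, config.dims
        T = config.hierarchy_levels
        depth = 2 if config.variant == "deep_lc" else 1

        self.first = nn.ConvBlock(1, f, d, rng, depth=depth)
        # per-level merge blocks for levels 1..T-1
        self.merges = []
        self.branches = []
        shared_branch = nn.ConvBlock(1, f, d, rng, depth=depth)
        for i in range(1, T):
            has_branch = config.lc_enabled and i <= config.L
            cin = f + (f if has_branch else 0)
            self.merges.append(nn.ConvBlock(cin, f, d, rng, depth=depth))
            if has_branch:
                self.branches.append(
                    nn.ConvBlock(1, f, d, rng, depth=depth)
                    if config.variant == "deep_lc" else shared_branch
                )
            else:
                self.branches.append(None)
        # top-down: posterior/prior parameter convs and td blocks per level
        self.q_convs = []
        self.p_convs = []
        self.td_blocks = []
        for i in range(T):
            top = i == T - 1
            q_in = f if top else f + z
            self.q_convs.append(nn.Conv(q_in, 2 * z, 3, d, rng, gain=0.2))
            self.p_convs.append(None if top else nn.Conv(z, 2 * z, 3, d, rng, gain=0.2))
            td_in = z if top else 2 * z
            self.td_blocks.append(nn.ConvBlock(td_in, z, d, rng, depth=depth))
        head_out = 2 * config.k_out if config.predict_logvar else config.k_out
        self.head = nn.Conv(z + f, head_out, 3, d, rng, gain=0.2)
        self.norm = NormStats(
            target_mean=np.zeros(config.k_out, np.float32),
            target_std=np.ones(config.k_out, np.float32),
        )

    # ------------------------------------------------------------------ #
    def _pool_factors(self):
        return (1, 2, 2) if self.config.dims == 3 else (2, 2)

    def _check_input(self, x):
        cfg = self.config
        expect_nd = 4 if cfg.dims == 2 else 5  # N, C, [Z,] H, W
        if x.ndim != expect_nd:
            raise ValueError(f"expected {expect_nd}-d input, got {x.ndim}-d")
        want = cfg.L + 1
        if x.shape[1] != want:
            raise ValueError(
                f"expected {want} input scales (primary + {cfg.L} contexts), "
                f"got {x.shape[1]}"
            )
        h, w = x.shape[-2:]
        div = 2 ** cfg.hierarchy_levels
        if h % div or w % div:
            raise ValueError(
                f"primary patch size {h}x{w} must be divisible by {div}"
            )

    def encode(self, x: Tensor):
        """Bottom-up pass. Returns per-level feature maps h[0..T-1]."""
        cfg = self.config
        self._check_input(x.data)
        primary = x[:, 0:1]
        feats = [self.first(primary)]
        spatial = x.data.shape[-2:]
        pf = self._pool_factors()
        for i in range(1, cfg.hierarchy_levels):
            pooled = nn.avg_pool(feats[-1], pf)
            if cfg.lc_enabled:
                pooled = nn.pad_center(pooled, spatial)
                branch = self.branches[i - 1]
                if branch is not None:
                    ctx = x[:, i : i + 1]
                    merged_in = nn.concat([pooled, branch(ctx)], axis=1)
                else:
                    merged_in = pooled
            else:
                merged_in = pooled
            feats.append(self.merges[i - 1](merged_in))
        return feats

    def decode(self, feats, mode: str = "sample", rng=None):
        """Top-down pass; returns (prediction, latents list indexed by level)."""
        cfg = self.config
        if mode not in ("sample", "posterior_mean"):
            raise ValueError("mode must be 'sample' or 'posterior_mean'")
        if mode == "sample" and rng is None:
            rng = np.random.default_rng(0)
        T = cfg.hierarchy_levels
        pf = self._pool_factors()
        latents: list[Optional[LevelLatents]] = [None] * T
        td = None
        for i in range(T - 1, -1, -1):
            h = feats[i]
            if i == T - 1:
                q_mu, q_lv = _split_mu_logvar(self.q_convs[i](h))
                p_mu = Tensor(np.zeros_like(q_mu.data))
                p_lv = Tensor(np.zeros_like(q_lv.data))
                td_up = None
            else:
                td_up = td if cfg.lc_enabled else nn.upsample_nearest(td, pf)
                p_mu, p_lv = _split_mu_logvar(self.p_convs[i](td_up))
                q_mu, q_lv = _split_mu_logvar(
                    self.q_convs[i](nn.concat([h, td_up], axis=1))
                )
            if mode == "sample":
                eps = rng.standard_normal(q_mu.shape).astype(np.float32)
                zi = q_mu + (q_lv * 0.5).exp() * Tensor(eps)
            else:
                zi = q_mu
            latents[i] = LevelLatents(q_mu, q_lv, p_mu, p_lv)
            td_in = zi if td_up is None else nn.concat([zi, td_up], axis=1)
            td = self.td_blocks[i](td_in)
        pred = self.head(nn.concat([td, feats[0]], axis=1))
        self._check_nan(pred)
        return pred, latents

    def forward(self, x, mode: str = "sample", rng=None):
        x = x if isinstance(x, Tensor) else Tensor(x)
        return self.decode(self.encode(x), mode=mode, rng=rng)

    @staticmethod
    def _check_nan(pred):
        if not np.all(np.isfinite(pred.data)):
            raise FloatingPointError("non-finite values in prediction head")

    # ------------------------------------------------------------------ #
    def no_lc_latent_shapes(self, primary_spatial):
        """Latent spatial shapes each level would have without LC inputs."""
        shapes = []
        for i in range(self.config.hierarchy_levels):
            if self.config.dims == 3:
                z, h, w = primary_spatial
                shapes.append((z, h // 2**i, w // 2**i))
            else:
                h, w = primary_spatial
                shapes.append((h // 2**i, w // 2**i))
        return shapes

    def predict_mean_logvar(self, pred: Tensor):
        """Split head output into (mean, logvar-or-None) tensors."""
        k = self.config.k_out
        if self.config.predict_logvar:
            return pred[:, :k], pred[:, k:]
        return pred, None


def build_model(config: ModelConfig) -> VSEModel:
    return VSEModel(config)


# --------------------------------------------------------------------------- #
# checkpointing
# --------------------------------------------------------------------------- #

CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: VSEModel, extra: dict | None = None):
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "norm": {
            "input_mean": float(model.norm.input_mean),
            "input_std": float(model.norm.input_std),
            "target_mean": model.norm.target_mean.tolist(),
            "target_std": model.norm.target_std.tolist(),
        },
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> VSEModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = ModelConfig(**meta["config"])
        model = VSEModel(cfg)
        n = len(model.parameters())
        model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    model.norm = NormStats(
        input_mean=meta["norm"]["input_mean"],
        input_std=meta["norm"]["input_std"],
        target_mean=np.asarray(meta["norm"]["target_mean"], np.float32),
        target_std=np.asarray(meta["norm"]["target_std"], np.float32),
    )
    return model
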