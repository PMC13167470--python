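"""Posterior sampling, MMSE / pixel-uncertainty estimation and inner-tiled
full-frame prediction.

Inner tiling: the frame is covered by overlapping tiles whose central crops
partition the output exactly once; edge tiles are shifted inward so their
centres still tile the frame.  Per tile, S posterior samples are drawn and
averaged before stitching (per-sample stitched frames can be retained for
calibration analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lc_patching import extract_lc_patch
from .vse import VSEModel


@dataclass
class PosteriorSampleSet:
    samples: np.ndarray  # (S, k, [Z,] H, W), raw intensity scale
    seed: int = 0

    def __post_init__(self):
        if self.samples.shape[0] < 1:
            raise ValueError("S must be >= 1")

    @property
    def S(self) -> int:
        return self.samples.shape[0]


@dataclass
class PredictionResult:
    mmse: np.ndarray
    rmse_estimate: Optional[np.ndarray] = None
    samples: Optional[np.ndarray] = None


# --------------------------------------------------------------------------- #

def _normalize_input(model: VSEModel, lc_arr: np.ndarray) -> np.ndarray:
    return (lc_arr - model.norm.input_mean) / model.norm.input_std


def _denormalize(model: VSEModel, mean_norm: np.ndarray) -> np.ndarray:
    k = model.config.k_out
    shape = (1, k) + (1,) * (mean_norm.ndim - 2)
    return mean_norm * model.norm.target_std.reshape(shape) + \
        model.norm.target_mean.reshape(shape)


def _forward_samples(model: VSEModel, lc_arr: np.ndarray, S: int, rng):
    """Batch the S posterior draws of one LC patch along the batch axis."""
    x = _normalize_input(model, lc_arr)[None].repeat(S, axis=0).astype(np.float32)
    pred, _ = model.forward(x, mode="sample", rng=rng)
    mean, _ = model.predict_mean_logvar(pred)
    return _denormalize(model, mean.data)  # (S, k, ...)


def sample_posterior(model: VSEModel, lc_arr: np.ndarray, S: int = 50,
                     seed: int = 0) -> PosteriorSampleSet:
    """Draw S independent posterior samples for one LC input patch."""
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    return PosteriorSampleSet(
        samples=_forward_samples(model, np.asarray(lc_arr, np.float32), S, rng),
        seed=seed,
    )


def mmse_and_uncertainty(samples: PosteriorSampleSet,
                         uncertainty_scale: float = 1.0) -> PredictionResult:
    """Pixel-wise mean and unbiased std over the posterior samples."""
    if samples.S < 2:
        raise ValueError("uncertainty estimation requires S >= 2")
    mmse = samples.samples.mean(axis=0)
    std = samples.samples.std(axis=0, ddof=1) * uncertainty_scale
    return PredictionResult(mmse=mmse, rmse_estimate=std, samples=samples.samples)


# --------------------------------------------------------------------------- #
# tiling
# --------------------------------------------------------------------------- #

def tile_plan(extent: int, tile: int, center: int):
    """1D inner-tiling plan: (center_start, write_lo, write_hi) triples whose
    write ranges partition [0, extent) exactly once."""
    if center > tile:
        raise ValueError("center_size must be <= tile_size")
    if extent < center:
        raise ValueError("frame smaller than center crop")
    plan = []
    prev_end = 0
    n_full = extent // center
    starts = [i * center for i in range(n_full)]
    if extent % center:
        starts.append(extent - center)
    for cs in starts:
        plan.append((cs, prev_end, min(cs + center, extent)))
        prev_end = cs + center
    return plan


def coverage_map(frame_shape, tile: int, center: int) -> np.ndarray:
    """How many times each output pixel is written; must be all-ones."""
    H, W = frame_shape[-2:]
    cov = np.zeros((H, W), dtype=np.int32)
    for _, ylo, yhi in tile_plan(H, tile, center):
        for _, xlo, xhi in tile_plan(W, tile, center):
            cov[ylo:yhi, xlo:xhi] += 1
    return cov


def tiled_predict(model, frame: np.ndarray, tile_size: int = 64,
                  center_size: int = 32, S: int = 50, seed: int = 0,
                  retain_samples: bool = False,
                  uncertainty_scale: float = 1.0) -> PredictionResult:
    """Full-frame prediction with inner tiling (defaults 64/32, 50 samples).

    ``model`` needs ``forward`` / ``predict_mean_logvar`` / ``norm`` /
    ``config`` (a trained VSEModel, or a deterministic stub in tests).
    LC contexts are extracted around each tile centre with reflective
    boundary handling.  Frames smaller than one tile are reflect-padded.
    """
    if tile_size % 2 or center_size % 2:
        raise ValueError("tile_size and center_size must be even")
    if center_size > tile_size:
        raise ValueError("center_size must be <= tile_size")
    frame = np.asarray(frame, dtype=np.float32)
    H, W = frame.shape[-2:]
    pad_y = max(tile_size - H, 0)
    pad_x = max(tile_size - W, 0)
    if pad_y or pad_x:
        padded = np.pad(frame, [(0, 0)] * (frame.ndim - 2)
                        + [(0, pad_y), (0, pad_x)], mode="reflect")
        res = tiled_predict(model, padded, tile_size, center_size, S, seed,
                            retain_samples, uncertainty_scale)
        sl = (..., slice(0, H), slice(0, W))
        return PredictionResult(
            mmse=res.mmse[sl], rmse_estimate=res.rmse_estimate[sl],
            samples=None if res.samples is None else res.samples[(slice(None),) + sl[1:]],
        )

    k = model.config.k_out
    L = model.config.L
    half = tile_size // 2
    margin = (tile_size - center_size) // 2
    mmse = np.zeros((k, H, W), dtype=np.float32)
    unc = np.zeros((k, H, W), dtype=np.float32)
    smp = np.zeros((S, k, H, W), dtype=np.float32) if retain_samples else None
    rng = np.random.default_rng(seed)

    for cy, ylo, yhi in tile_plan(H, tile_size, center_size):
        t0y = min(max(cy - margin, 0), H - tile_size)
        for cx, xlo, xhi in tile_plan(W, tile_size, center_size):
            t0x = min(max(cx - margin, 0), W - tile_size)
            lc = extract_lc_patch(
                frame, (t0y + half, t0x + half), tile_size, L, pad_mode="reflect"
            )
            preds = _forward_samples(model, lc.as_array(), S, rng)
            wy = slice(ylo - t0y, yhi - t0y)
            wx = slice(xlo - t0x, xhi - t0x)
            mmse[:, ylo:yhi, xlo:xhi] = preds.mean(axis=0)[:, wy, wx]
            if S >= 2:
                unc[:, ylo:yhi, xlo:xhi] = (
                    preds.std(axis=0, ddof=1)[:, wy, wx] * uncertainty_scale
                )
            if retain_samples:
                smp[:, :, ylo:yhi, xlo:xhi] = preds[:, :, wy, wx]

    return PredictionResult(mmse=mmse,
                            rmse_estimate=unc if S >= 2 else None,
                            samples=smp)
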