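"""Synthetic multi-structure micrographs and training-pair assembly.

Four structure archetypes (filaments, blobs, puncta, rings) stand in for the
structurally distinct organelle channels of real multiplexed acquisitions.
Training inputs are built in one of four modes:

* mode I   — sum of co-located channel crops (spatial correlations kept),
* mode II  — sum of crops from independent locations (correlations destroyed),
* mode IIb — random sums of small manually-cropped pure-structure regions,
* mode III — a separately "acquired" superimposed channel with its own noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

StructureKind = Literal["filaments", "blobs", "puncta", "rings"]

SCALED_COPY_FACTORS = (1.032, 1.063, 1.125, 1.25, 1.5, 2.0)


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class ChannelStack:
    """k-channel intensity stack of shape (k, [Z,] H, W), photon-count scale."""

    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    voxel_size: Optional[tuple[float, ...]] = None
    is_noisy: Optional[list[bool]] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must have shape (k, [Z,] H, W)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        k = self.data.shape[0]
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(k)]
        if len(self.channel_names) != k:
            raise ValueError("channel_names length must equal channel count")
        if self.is_noisy is None:
            self.is_noisy = [False] * k
        if len(self.is_noisy) != k:
            raise ValueError("is_noisy length must equal channel count")

    @property
    def k(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]


@dataclass
class NoiseSpec:
    """Poisson-Gaussian observation noise.

    ``poisson_scale`` is the photon-conversion factor (0 disables shot noise);
    ``gaussian_sigma`` is additive read-noise std in intensity units.
    """

    gaussian_sigma: float = 0.0
    poisson_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.poisson_scale < 0:
            raise ValueError("poisson_scale must be >= 0")


@dataclass
class MixTask:
    """Description of one unmixing task family."""

    k: int
    weights: Sequence[float]
    mode: Literal["I", "II", "IIb", "III"] = "I"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    similarity_scale: Optional[float] = None

    def __post_init__(self):
        if self.k not in (2, 3, 4):
            raise ValueError("k must be in {2, 3, 4}")
        if len(self.weights) != self.k:
            raise ValueError("weights length must equal k")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be > 0")
        if self.similarity_scale is not None:
            if self.k != 2:
                raise ValueError("similarity_scale only valid for k = 2")
            if self.similarity_scale < 1:
                raise ValueError("similarity_scale must be >= 1 (swap channels)")


# --------------------------------------------------------------------------- #
# structure generators
# --------------------------------------------------------------------------- #

_AMP_RANGE = (50.0, 100.0)


def _check_shape(shape):
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2:
        raise ValueError("generators are 2D; stack slices for 3D phantoms")
    if min(shape) < 32:
        raise ValueError("all spatial dims must be >= 32")
    return shape


def _filaments(shape, density, rng):
    img = np.zeros(shape, dtype=np.float32)
    n = rng.poisson(density * shape[0] * shape[1])
    for _ in range(n):
        y, x = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        angle = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(*_AMP_RANGE)
        length = int(rng.uniform(0.3, 0.9) * min(shape))
        for _ in range(length):
            iy, ix = int(y), int(x)
            if 0 <= iy < shape[0] and 0 <= ix < shape[1]:
                img[iy, ix] = max(img[iy, ix], amp)
            angle += rng.normal(0, 0.15)
            y += np.sin(angle)
            x += np.cos(angle)
    return ndimage.gaussian_filter(img, 0.7)


def _blobs(shape, density, rng):
    img = np.zeros(shape, dtype=np.float32)
    n = rng.poisson(density * shape[0] * shape[1])
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float32)
    for _ in range(n):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        ry = rng.uniform(4, 10)
        rx = rng.uniform(4, 10)
        amp = rng.uniform(*_AMP_RANGE)
        d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        img = np.maximum(img, amp * (d2 < 1.0).astype(np.float32))
    return ndimage.gaussian_filter(img, 1.5)


def _puncta(shape, density, rng):
    img = np.zeros(shape, dtype=np.float32)
    n = rng.poisson(density * shape[0] * shape[1])
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float32)
    for _ in range(n):
        cy, cx = rng.uniform(2, shape[0] - 2), rng.uniform(2, shape[1] - 2)
        sig = rng.uniform(1.4, 2.4)
        amp = rng.uniform(*_AMP_RANGE)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += amp * np.exp(-d2 / (2 * sig * sig))
    return img


def _rings(shape, density, rng):
    img = np.zeros(shape, dtype=np.float32)
    n = rng.poisson(density * shape[0] * shape[1])
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float32)
    for _ in range(n):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        radius = rng.uniform(5, 14)
        thick = rng.uniform(1.0, 2.5)
        amp = rng.uniform(*_AMP_RANGE)
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        img = np.maximum(img, amp * np.exp(-((d - radius) ** 2) / (2 * thick**2)))
    return img


_GENERATORS = {
    "filaments": _filaments,
    "blobs": _blobs,
    "puncta": _puncta,
    "rings": _rings,
}


def generate_structure_channel(
    kind: StructureKind, shape, density: float, seed: int
) -> ChannelStack:
    """Draw a single clean structure channel on a zero background."""
    if kind not in _GENERATORS:
        raise ValueError(f"unknown structure kind {kind!r}")
    if density < 0:
        raise ValueError("density must be >= 0")
    shape = _check_shape(shape)
    rng = np.random.default_rng(seed)
    img = _GENERATORS[kind](shape, density, rng).astype(np.float32)
    return ChannelStack(img[None], channel_names=[kind])


def generate_colocalized_pair(shape, density: float, rho: float, seed: int) -> ChannelStack:
    """Two blob-like channels with a tunable intensity colocalization ~rho.

    Channel B shares a fraction of channel A's structure so that the pixel-wise
    Pearson correlation is approximately ``rho`` — the mode-I/II contrast probe.
    """
    rng = np.random.default_rng(seed)
    a = _blobs(shape, density, rng)
    b_own = _blobs(shape, density, rng)
    sa, sb = a.std() + 1e-12, b_own.std() + 1e-12
    b = rho * (a / sa) + np.sqrt(max(1 - rho * rho, 0.0)) * (b_own / sb)
    b = np.clip(b, 0, None) * sb
    return ChannelStack(np.stack([a, b]), channel_names=["a", "b"])


# --------------------------------------------------------------------------- #
# mixing and noise
# --------------------------------------------------------------------------- #

def mix_channels(channels: ChannelStack, weights: Sequence[float]) -> np.ndarray:
    """Pixel-wise weighted sum of the channels into one superimposed image."""
    w = np.asarray(weights, dtype=np.float32)
    if w.shape != (channels.k,):
        raise ValueError(f"expected {channels.k} weights, got {w.shape}")
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    return np.tensordot(w, channels.data, axes=(0, 0)).astype(np.float32)


def apply_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Poisson shot noise (photon-conversion `poisson_scale`) plus Gaussian
    read noise; identity when both are disabled."""
    img = np.asarray(image, dtype=np.float32)
    rng = np.random.default_rng(spec.seed)
    out = img
    if spec.poisson_scale > 0:
        if np.any(img < 0):
            raise ValueError("shot noise requires a non-negative clean image")
        out = rng.poisson(img / spec.poisson_scale).astype(np.float32) * spec.poisson_scale
    if spec.gaussian_sigma > 0:
        out = out + rng.normal(0.0, spec.gaussian_sigma, size=img.shape).astype(np.float32)
    return out.astype(np.float32)


# --------------------------------------------------------------------------- #
# training-pair assembly (modes I / II / IIb / III)
# --------------------------------------------------------------------------- #

def _crop(arr, top_left, size):
    (y, x), (h, w) = top_left, size
    if y < 0 or x < 0 or y + h > arr.shape[-2] or x + w > arr.shape[-1]:
        raise ValueError("crop outside frame")
    return arr[..., y : y + h, x : x + w]


def assemble_mode_I(stack: ChannelStack, top_left=(0, 0), size=None,
                    weights=None):
    """Co-located crops: input is the weighted sum of the target crops."""
    if size is None:
        size = stack.spatial_shape[-2:]
    targets = _crop(stack.data, top_left, size)
    w = np.ones(stack.k, np.float32) if weights is None else np.asarray(weights, np.float32)
    if w.shape != (stack.k,):
        raise ValueError("weight count mismatch")
    inp = np.tensordot(w, targets, axes=(0, 0)).astype(np.float32)
    return inp, targets


def assemble_mode_II(stacks: Sequence[ChannelStack], size, seed: int,
                     weights=None):
    """Independent random crop per channel (from per-structure sources), summed.

    Destroys any cross-channel spatial correlation in expectation.
    """
    if len(stacks) < 1:
        raise ValueError("need at least one source per channel")
    for s in stacks:
        if s.k != 1:
            raise ValueError("mode II sources must be single-channel")
    rng = np.random.default_rng(seed)
    h, w_ = size
    crops = []
    for s in stacks:
        H, W = s.spatial_shape[-2:]
        if h > H or w_ > W:
            raise ValueError("patch larger than frame")
        y = int(rng.integers(0, H - h + 1))
        x = int(rng.integers(0, W - w_ + 1))
        crops.append(_crop(s.data[0], (y, x), size))
    targets = np.stack(crops).astype(np.float32)
    k = len(stacks)
    wts = np.ones(k, np.float32) if weights is None else np.asarray(weights, np.float32)
    inp = np.tensordot(wts, targets, axes=(0, 0)).astype(np.float32)
    return inp, targets


def assemble_mode_IIb(pure_regions_a: Sequence[np.ndarray],
                      pure_regions_b: Sequence[np.ndarray], seed: int):
    """Randomly pair one pure-structure crop of each class and sum them.

    Crops may be small (down to ~100x100 px in the motivating use case), which
    is why lateral-context inputs must stay disabled for this mode.
    """
    if len(pure_regions_a) == 0 or len(pure_regions_b) == 0:
        raise ValueError("both crop lists must be non-empty")
    rng = np.random.default_rng(seed)
    ia = int(rng.integers(0, len(pure_regions_a)))
    ib = int(rng.integers(0, len(pure_regions_b)))
    a = np.asarray(pure_regions_a[ia], dtype=np.float32)
    b = np.asarray(pure_regions_b[ib], dtype=np.float32)
    h = min(a.shape[0], b.shape[0])
    w = min(a.shape[1], b.shape[1])
    a, b = a[:h, :w], b[:h, :w]
    targets = np.stack([a, b])
    return (a + b).astype(np.float32), targets, (ia, ib)


def assemble_mode_III(stack: ChannelStack, top_left=(0, 0), size=None):
    """Targets plus a separately acquired superimposed input channel.

    The stack's last channel is treated as the acquired input; its noise is
    independent of the target noise by construction.
    """
    if stack.k < 2:
        raise ValueError("mode III needs target channels plus a superimposed channel")
    if size is None:
        size = stack.spatial_shape[-2:]
    targets = _crop(stack.data[:-1], top_left, size)
    inp = _crop(stack.data[-1], top_left, size)
    return inp.astype(np.float32), targets.astype(np.float32)


def make_mode_III_stack(clean: ChannelStack, noise: NoiseSpec) -> ChannelStack:
    """Simulated mode-III acquisition: noisy targets plus the clean sum under a
    fresh, independent noise realization as the acquired input channel."""
    noisy_targets = [
        apply_noise(clean.data[c], NoiseSpec(noise.gaussian_sigma,
                                             noise.poisson_scale,
                                             seed=noise.seed + 1 + c))
        for c in range(clean.k)
    ]
    acquired = apply_noise(clean.data.sum(axis=0),
                           NoiseSpec(noise.gaussian_sigma, noise.poisson_scale,
                                     seed=noise.seed))
    data = np.stack(noisy_targets + [acquired])
    return ChannelStack(
        data,
        channel_names=clean.channel_names + ["superimposed"],
        is_noisy=[True] * (clean.k + 1),
    )


def make_scaled_copy_task(source: ChannelStack, s: float, size, seed: int) -> ChannelStack:
    """Two structurally identical channels, the second intensity-scaled by s.

    Patches are taken at independent locations of the same source channel; at
    s = 1 the two channels are draws from the identical distribution (the
    provably ambiguous case).
    """
    if source.k != 1:
        raise ValueError("source must be single-channel")
    if s < 1:
        raise ValueError("s must be >= 1; swap channels to normalize")
    rng = np.random.default_rng(seed)
    H, W = source.spatial_shape[-2:]
    h, w = size
    if h > H or w > W:
        raise ValueError("patch larger than source frame")
    crops = []
    for _ in range(2):
        y = int(rng.integers(0, H - h + 1))
        x = int(rng.integers(0, W - w + 1))
        crops.append(source.data[0, y : y + h, x : x + w])
    data = np.stack([crops[0], np.float32(s) * crops[1]])
    return ChannelStack(data, channel_names=["copy", f"copy_x{s:g}"])
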