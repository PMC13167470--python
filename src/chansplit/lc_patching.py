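"""Primary-patch extraction with lateral-context (LC) pyramids.

Context level l covers a window 2^l times larger than the primary patch,
centred on it, and is area-averaged down to the primary patch's pixel
dimensions.  For 3D data the pyramid applies laterally (H, W) only; Z is
passed through at native resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantoms import MixTask


@dataclass
class LCPatch:
    """Primary input patch plus L downscaled context patches of identical
    pixel dimensions, all centred on the primary patch."""

    primary: np.ndarray
    contexts: list[np.ndarray] = field(default_factory=list)
    center: tuple[int, ...] = ()

    @property
    def L(self) -> int:
        return len(self.contexts)

    def as_array(self) -> np.ndarray:
        """(1 + L, [Z,] h, w) array: primary first, then contexts."""
        return np.stack([self.primary, *self.contexts])


def _block_average(arr: np.ndarray, factor: int) -> np.ndarray:
    """Area-average downscale of the trailing two axes by an integer factor."""
    h, w = arr.shape[-2:]
    if h % factor or w % factor:
        raise ValueError("downscale factor must divide window size")
    shape = arr.shape[:-2] + (h // factor, factor, w // factor, factor)
    return arr.reshape(shape).mean(axis=(-3, -1))


def extract_lc_patch(frame: np.ndarray, center, primary_size: int, L: int,
                     pad_mode: str = "reflect") -> LCPatch:
    """Extract the primary patch and L context levels around ``center``.

    ``frame`` is ([Z,] H, W); ``center`` the (y, x) centre in frame
    coordinates. Context level l crops the (2^l * primary_size) window and
    block-averages it by 2^l.  Boundaries are handled by ``pad_mode`` padding
    of the frame; the primary window itself must fit inside the frame.
    """
    if primary_size % 2:
        raise ValueError("primary_size must be even")
    if L < 0:
        raise ValueError("L must be >= 0")
    frame = np.asarray(frame, dtype=np.float32)
    cy, cx = int(center[-2]), int(center[-1])
    half = primary_size // 2
    H, W = frame.shape[-2:]
    if cy - half < 0 or cx - half < 0 or cy + half > H or cx + half > W:
        raise ValueError("primary window outside frame")
    primary = frame[..., cy - half : cy + half, cx - half : cx + half].copy()

    contexts = []
    if L > 0:
        maxhalf = half * 2 ** L
        padspec = [(0, 0)] * (frame.ndim - 2) + [(maxhalf, maxhalf)] * 2
        padded = np.pad(frame, padspec, mode=pad_mode)
        py, px = cy + maxhalf, cx + maxhalf
        for level in range(1, L + 1):
            hw = half * 2 ** level
            win = padded[..., py - hw : py + hw, px - hw : px + hw]
            contexts.append(_block_average(win, 2 ** level).astype(np.float32))
    return LCPatch(primary=primary, contexts=contexts, center=(cy, cx))


def lowres_count_to_L(multiscale_lowres_count: int) -> int:
    """Config convention: a lowres count of n means n - 1 context levels
    (the primary input is counted as the first scale)."""
    if multiscale_lowres_count < 1:
        raise ValueError("multiscale_lowres_count must be >= 1")
    return multiscale_lowres_count - 1


@dataclass
class PatchBatch:
    inputs: np.ndarray      # (n, 1 + L, h, w)
    targets: np.ndarray     # (n, k, h, w)
    centers: np.ndarray     # (n, 2)


def sample_training_patches(stacks, task: MixTask, patch_size: int, n: int,
                            seed: int, L: int = 1,
                            noisy_stacks=None) -> PatchBatch:
    """Sample n aligned (LC input, k targets) pairs per the active mode.

    ``stacks``: a ChannelStack (modes I/III) or a list of single-channel
    ChannelStacks (mode II). Mode IIb forces L = 0 (crops are too small for
    context pyramids).  ``noisy_stacks`` optionally provides the noisy target
    realization aligned with ``stacks`` (mode I on noisy data).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if task.mode == "IIb" and L != 0:
        raise ValueError("mode IIb requires L = 0 (LC disabled)")
    rng = np.random.default_rng(seed)
    half = patch_size // 2
    weights = np.asarray(task.weights, dtype=np.float32)

    inputs, targets, centers = [], [], []
    if task.mode in ("I", "III"):
        stack = stacks
        H, W = stack.spatial_shape[-2:]
        if patch_size > H or patch_size > W:
            raise ValueError("patch larger than frame")
        tgt_src = stack.data if noisy_stacks is None else noisy_stacks.data
        if task.mode == "III":
            if stack.k < 2:
                raise ValueError("mode III needs a superimposed channel")
            mixed = stack.data[-1]
            tgt_all = tgt_src[:-1]
        else:
            # mode I: the input is the weighted sum of the recorded target
            # channels themselves (noisy if the targets are noisy)
            tgt_all = tgt_src
            mixed = np.tensordot(weights, tgt_all, axes=(0, 0))
        for _ in range(n):
            cy = int(rng.integers(half, H - half + 1))
            cx = int(rng.integers(half, W - half + 1))
            lc = extract_lc_patch(mixed, (cy, cx), patch_size, L)
            inputs.append(lc.as_array())
            targets.append(
                tgt_all[:, cy - half : cy + half, cx - half : cx + half]
            )
            centers.append((cy, cx))
    elif task.mode == "II":
        if len(stacks) < task.k:
            raise ValueError(f"mode II needs >= {task.k} single-channel sources")
        for _ in range(n):
            crops, mixes = [], []
            for c in range(task.k):
                s = stacks[c]
                H, W = s.spatial_shape[-2:]
                cy = int(rng.integers(half, H - half + 1))
                cx = int(rng.integers(half, W - half + 1))
                lc = extract_lc_patch(s.data[0], (cy, cx), patch_size, L)
                crops.append(lc)
            tgt = np.stack([c.primary for c in crops])
            inp = np.stack(
                [np.tensordot(weights,
                              np.stack([c.primary if lvl == 0 else c.contexts[lvl - 1]
                                        for c in crops]), axes=(0, 0))
                 for lvl in range(L + 1)]
            )
            inputs.append(inp)
            targets.append(tgt)
            centers.append(crops[0].center)
    else:
        raise ValueError(f"unsupported sampling mode {task.mode!r}")

    return PatchBatch(
        inputs=np.stack(inputs).astype(np.float32),
        targets=np.stack(targets).astype(np.float32),
        centers=np.asarray(centers),
    )
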