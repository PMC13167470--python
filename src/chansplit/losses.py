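"""Training objective: weighted combination of a noise-model (denoising)
likelihood branch and a direct Gaussian-reconstruction branch, plus the
hierarchy KL terms.

The KL at each level is computed pixel-wise in closed form, centre-cropped to
the spatial shape the latent would have had without lateral-context inputs
(which inflate latent maps to the primary patch size), scaled by alpha and
summed.  For volumetric latents the pixel-wise KL is first averaged along Z,
making the KL contribution invariant to the number of input z-slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .noise_model import NoiseModel
from .vse import LevelLatents, NormStats

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LossConfig:
    w: float = 0.9
    alpha: Optional[float] = None  # None -> 1 / (cropped spatial pixels) per level
    kl_free_nats: float = 0.0
    likelihood_variance_mode: Literal["fixed", "learned"] = "learned"
    fixed_sigma: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.kl_free_nats < 0:
            raise ValueError("kl_free_nats must be >= 0")


# --------------------------------------------------------------------------- #
# KL machinery
# --------------------------------------------------------------------------- #

def kl_elementwise(lat: LevelLatents) -> Tensor:
    """Closed-form KL(q || p) between diagonal Gaussians, per element."""
    if lat.q_mu.shape != lat.p_mu.shape:
        raise ValueError("posterior/prior shape mismatch")
    dlv = lat.q_logvar - lat.p_logvar
    var_ratio = dlv.exp()
    dmu2 = (lat.q_mu - lat.p_mu) ** 2.0 * (-lat.p_logvar).exp()
    return (var_ratio + dmu2 - 1.0 - dlv) * 0.5


def kl_per_level(latents: Sequence[LevelLatents]) -> list[Tensor]:
    return [kl_elementwise(lat) for lat in latents]


def _resolve_alpha(alpha, target_shape):
    if alpha is not None:
        return float(alpha)
    return 1.0 / float(np.prod(target_shape))


def kl_loss_cropped(kl: Tensor, target_shape, alpha: Optional[float] = None) -> Tensor:
    """alpha * sum over channels and the centre-cropped spatial window,
    computed per batch element and averaged over the batch."""
    nd = len(target_shape)
    if any(t > s for t, s in zip(target_shape, kl.shape[-nd:])):
        raise ValueError("crop target larger than KL tensor")
    a = _resolve_alpha(alpha, target_shape)
    cropped = nn.center_crop(kl, tuple(target_shape))
    n = kl.shape[0]
    return cropped.sum() * (a / n)


def kl_loss_3d(kl: Tensor, target_shape, alpha: Optional[float] = None) -> Tensor:
    """Volumetric variant: average the (N, C, Z, H, W) KL along Z, then apply
    the centre-cropped 2D reduction.  Invariant to z-replication."""
    if kl.ndim != 5:
        raise ValueError("expected (N, C, Z, H, W) KL tensor")
    n, c, z, h, w = kl.shape
    zavg = nn.avg_pool(kl, (z, 1, 1)).reshape(n, c, h, w)
    return kl_loss_cropped(zavg, target_shape, alpha)


def total_kl(latents, no_lc_shapes, cfg: LossConfig, dims: int = 2) -> tuple[Tensor, list[float]]:
    """Sum of per-level cropped KL terms (z-averaged first when dims == 3)."""
    terms = []
    for lat, shape in zip(kl_per_level(latents), no_lc_shapes):
        if dims == 3:
            tgt2d = shape[-2:]
            term = kl_loss_3d(lat, tgt2d, cfg.alpha)
        else:
            term = kl_loss_cropped(lat, shape, cfg.alpha)
        if cfg.kl_free_nats > 0 and term.data < cfg.kl_free_nats:
            term = Tensor(np.float32(cfg.kl_free_nats))
        terms.append(term)
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out, [float(t.data) for t in terms]


# --------------------------------------------------------------------------- #
# likelihood branches
# --------------------------------------------------------------------------- #

def gaussian_branch_nll(mean: Tensor, target: np.ndarray,
                        logvar: Optional[Tensor] = None,
                        fixed_sigma: float = 1.0) -> Tensor:
    """Direct-reconstruction branch: Gaussian negative log-likelihood of the
    (noisy) target under the predicted mean, summed over the primary patch
    and averaged over the batch.  With ``logvar=None`` the variance is fixed,
    reducing to MSE / (2 sigma^2) plus a constant."""
    if not np.all(np.isfinite(mean.data)):
        raise FloatingPointError("non-finite prediction")
    t = Tensor(np.asarray(target, np.float32))
    n = mean.shape[0]
    if logvar is None:
        s2 = float(fixed_sigma) ** 2
        quad = ((t - mean) ** 2.0).sum() * (0.5 / s2)
        const = 0.5 * (LOG2PI + np.log(s2)) * (mean.data.size / n)
        return quad * (1.0 / n) + const
    nll = (logvar + ((t - mean) ** 2.0) * (-logvar).exp() + LOG2PI) * 0.5
    return nll.sum() * (1.0 / n)


def noise_model_branch_nll(pred_signal: Tensor, target: np.ndarray,
                           model: NoiseModel) -> Tensor:
    """Denoising branch: negative log-likelihood of the noisy target under
    the clean-signal prediction according to the observation noise model.

    The noise model supplies both the value and its derivative with respect
    to the signal, spliced into the autodiff graph."""
    if model is None:
        raise ValueError("noise model required for the denoising branch")
    obs = np.asarray(target, np.float64)
    ll = model.loglikelihood(obs, pred_signal.data)
    dll = model.dloglik_dsignal(obs, pred_signal.data)
    n = pred_signal.shape[0]
    value = np.float32(-ll.sum() / n)
    grad = (-dll / n).astype(np.float32)
    return nn.custom_grad(value, [pred_signal], {pred_signal: grad})


# --------------------------------------------------------------------------- #
# combined objective
# --------------------------------------------------------------------------- #

def combined_loss(pred: Tensor, target_norm: np.ndarray,
                  latents: Sequence[LevelLatents],
                  noise_model: Optional[NoiseModel], cfg: LossConfig,
                  no_lc_shapes, norm: Optional[NormStats] = None,
                  target_raw: Optional[np.ndarray] = None,
                  k_out: Optional[int] = None, dims: int = 2):
    """loss = w * denoising branch + (1 - w) * reconstruction branch, each
    branch being its likelihood term plus the summed cropped KL.

    Returns (scalar loss Tensor, per-term breakdown dict).  ``pred`` is the
    raw head output (mean, or mean+logvar stacked along channels) in
    normalized target space; ``target_norm`` likewise.  The denoising branch
    is evaluated in raw intensity space using ``norm`` and ``target_raw``.
    """
    k = k_out if k_out is not None else target_norm.shape[1]
    if pred.shape[1] == 2 * k:
        mean, logvar = pred[:, :k], pred[:, k:]
    else:
        mean, logvar = pred, None

    kl_total, kl_terms = total_kl(latents, no_lc_shapes, cfg, dims=dims)

    use_learned = cfg.likelihood_variance_mode == "learned" and logvar is not None
    nll_mu = gaussian_branch_nll(
        mean, target_norm, logvar if use_learned else None, cfg.fixed_sigma
    )

    if cfg.w > 0:
        if norm is None:
            norm = NormStats(target_mean=np.zeros(k, np.float32),
                             target_std=np.ones(k, np.float32))
        if target_raw is None:
            raise ValueError("denoising branch requires the raw noisy target")
        shape = (1, k) + (1,) * (mean.ndim - 2)
        std = Tensor(norm.target_std.reshape(shape))
        mu = Tensor(norm.target_mean.reshape(shape))
        pred_raw = mean * std + mu
        nll_d = noise_model_branch_nll(pred_raw, target_raw, model=noise_model)
    else:
        nll_d = Tensor(np.float32(0.0))

    loss = nll_d * cfg.w + nll_mu * (1.0 - cfg.w) + kl_total
    breakdown = {
        "loss": float(loss.data),
        "nll_denoise": float(nll_d.data),
        "nll_gaussian": float(nll_mu.data),
        "kl_total": float(kl_total.data),
        "kl_per_level": kl_terms,
        "w": cfg.w,
    }
    return loss, breakdown
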