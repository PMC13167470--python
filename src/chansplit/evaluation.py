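"""Range-invariant microscopy metrics and the RMV-vs-RMSE calibration
analysis.

Both metrics first fit a least-squares affine map (scale + offset) of the
prediction onto the reference, making them invariant to affine intensity
transforms of the prediction — appropriate for unmixing outputs whose
absolute scale is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

PSNR_CAP_DB = 100.0

MS_SSIM_SCALES = 3
MS_SSIM_WINDOW = 7


def _affine_fit(pred: np.ndarray, ref: np.ndarray):
    """Least-squares (a, b) minimizing ||a * pred + b - ref||^2."""
    p = pred.astype(np.float64).ravel()
    r = ref.astype(np.float64).ravel()
    vp = p.var()
    if vp < 1e-300:
        return 0.0, r.mean()
    a = ((p - p.mean()) * (r - r.mean())).mean() / vp
    b = r.mean() - a * p.mean()
    return a, b


def care_psnr(pred: np.ndarray, reference: np.ndarray) -> float:
    """PSNR after affine (scale + offset) fit of pred to reference, using the
    reference dynamic range; capped at 100 dB for exact matches."""
    pred = np.asarray(pred, np.float64)
    ref = np.asarray(reference, np.float64)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    rng = ref.max() - ref.min()
    if rng <= 0:
        raise ValueError("constant reference")
    a, b = _affine_fit(pred, ref)
    mse = ((a * pred + b - ref) ** 2).mean()
    if mse <= (rng * 10 ** (-PSNR_CAP_DB / 20.0)) ** 2:
        return PSNR_CAP_DB
    return float(20.0 * np.log10(rng / np.sqrt(mse)))


def micro_ms_ssim(pred: np.ndarray, reference: np.ndarray,
                  scales: int = MS_SSIM_SCALES,
                  window: int = MS_SSIM_WINDOW) -> float:
    """Multi-scale SSIM after affine normalization of pred to the reference.

    Equal scale weights (arithmetic mean over scales); each scale halves the
    resolution by block averaging.  An approximation of the microscopy-
    adapted SSIM variants: same invariances, fixed documented parameters.
    """
    pred = np.asarray(pred, np.float64)
    ref = np.asarray(reference, np.float64)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    min_side = window * 2 ** (scales - 1)
    if min(pred.shape[-2:]) < min_side:
        raise ValueError(f"image too small for {scales}-scale pyramid "
                         f"(needs >= {min_side} px)")
    rng = ref.max() - ref.min()
    if rng <= 0:
        raise ValueError("constant reference")
    a, b = _affine_fit(pred, ref)
    p = a * pred + b
    r = ref.copy()
    vals = []
    for s in range(scales):
        vals.append(structural_similarity(
            p, r, win_size=window, data_range=r.max() - r.min() + 1e-12,
            gaussian_weights=False,
        ))
        if s < scales - 1:
            p = _halve(p)
            r = _halve(r)
    return float(np.mean(vals))


def _halve(img: np.ndarray) -> np.ndarray:
    h, w = img.shape[-2:]
    img = img[..., : h - h % 2, : w - w % 2]
    sh = img.shape[:-2] + (img.shape[-2] // 2, 2, img.shape[-1] // 2, 2)
    return img.reshape(sh).mean(axis=(-3, -1))


# --------------------------------------------------------------------------- #
# calibration
# --------------------------------------------------------------------------- #

@dataclass
class CalibrationCurve:
    bin_edges: np.ndarray
    rmv: np.ndarray
    rmse: np.ndarray
    counts: np.ndarray
    slope: Optional[float]
    intercept: Optional[float]
    rank_correlation: Optional[float]
    degenerate: bool = False


def calibration_analysis(rmse_estimate: np.ndarray, mmse: np.ndarray,
                         reference: np.ndarray, n_bins: int = 20) -> CalibrationCurve:
    """Bin pixels by predicted-uncertainty quantiles; per bin compute
    RMV = sqrt(mean predicted variance) and RMSE = sqrt(mean squared error of
    the MMSE prediction); summarize with a least-squares slope and Spearman
    rank correlation of RMSE against RMV."""
    if reference is None:
        raise ValueError("reference required for calibration analysis")
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    u = np.asarray(rmse_estimate, np.float64).ravel()
    m = np.asarray(mmse, np.float64).ravel()
    r = np.asarray(reference, np.float64).ravel()
    if not (u.size == m.size == r.size):
        raise ValueError("frames must be aligned")
    edges = np.quantile(u, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return CalibrationCurve(
            bin_edges=edges, rmv=np.array([np.sqrt((u**2).mean())]),
            rmse=np.array([np.sqrt(((m - r) ** 2).mean())]),
            counts=np.array([u.size]), slope=None, intercept=None,
            rank_correlation=None, degenerate=True,
        )
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, len(edges) - 2)
    rmv, rmse, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        rmv.append(np.sqrt((u[mask] ** 2).mean()))
        rmse.append(np.sqrt(((m[mask] - r[mask]) ** 2).mean()))
        counts.append(int(mask.sum()))
    rmv, rmse = np.asarray(rmv), np.asarray(rmse)
    slope, intercept = np.polyfit(rmv, rmse, 1)
    rho = stats.spearmanr(rmv, rmse).statistic
    return CalibrationCurve(
        bin_edges=edges, rmv=rmv, rmse=rmse,
        counts=np.asarray(counts, np.int64),
        slope=float(slope), intercept=float(intercept),
        rank_correlation=float(rho),
    )


def fit_calibration_scale(rmse_estimate: np.ndarray, mmse: np.ndarray,
                          reference: np.ndarray, n_bins: int = 20) -> float:
    """Scalar factor minimizing sum_b (RMSE_b - factor * RMV_b)^2."""
    curve = calibration_analysis(rmse_estimate, mmse, reference, n_bins)
    if curve.degenerate or np.sum(curve.rmv**2) < 1e-300:
        raise ValueError("degenerate bins: cannot fit a calibration scale")
    return float(np.sum(curve.rmse * curve.rmv) / np.sum(curve.rmv**2))
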