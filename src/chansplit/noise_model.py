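"""Pixel-wise observation-likelihood models p(noisy | clean).

Three families are provided:

* ``GaussianNoiseModel`` — constant read noise, closed form;
* ``PoissonGaussianNoiseModel`` — analytic Gaussian approximation with
  signal-dependent variance ``sigma^2 + scale * signal``;
* ``SignalDependentGMM`` — a Gaussian mixture whose per-component weight,
  mean-offset and log-std are polynomials of the (normalized) signal level,
  fitted from co-registered (reference, noisy) calibration pairs.

All models expose the log-likelihood and its derivative with respect to the
clean signal, which is what the denoising branch of the training loss needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

_LOG2PI = float(np.log(2.0 * np.pi))


class NoiseModel:
    """Interface: loglikelihood / dloglik_dsignal over a valid signal range."""

    signal_range: tuple[float, float]

    def _clamp(self, signal):
        lo, hi = self.signal_range
        return np.clip(signal, lo, hi)

    def _inside(self, signal):
        """1 where the signal is strictly inside the valid range, else 0 —
        the derivative of the clamp applied before evaluation."""
        lo, hi = self.signal_range
        return ((signal > lo) & (signal < hi)).astype(np.float64)

    def loglikelihood(self, observation, signal):  # pragma: no cover
        raise NotImplementedError

    def dloglik_dsignal(self, observation, signal):  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover
        raise NotImplementedError

    def save(self, path):
        with open(path, "w") as fh:
            json.dump({"format_version": 1, **self.to_dict()}, fh)


def load_noise_model(path) -> NoiseModel:
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("kind")
    if kind == "gaussian":
        return GaussianNoiseModel(d["sigma"], tuple(d["signal_range"]))
    if kind == "poisson_gaussian":
        return PoissonGaussianNoiseModel(
            d["gaussian_sigma"], d["poisson_scale"], tuple(d["signal_range"])
        )
    if kind == "gmm":
        return SignalDependentGMM(
            np.asarray(d["weight_coeffs"]),
            np.asarray(d["offset_coeffs"]),
            np.asarray(d["logstd_coeffs"]),
            tuple(d["signal_range"]),
            d["min_std"],
        )
    raise ValueError(f"unknown noise model kind {kind!r}")


# --------------------------------------------------------------------------- #

@dataclass
class GaussianNoiseModel(NoiseModel):
    sigma: float
    signal_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def loglikelihood(self, observation, signal):
        obs = np.asarray(observation, dtype=np.float64)
        sig = self._clamp(np.asarray(signal, dtype=np.float64))
        if np.any(~np.isfinite(obs)) or np.any(~np.isfinite(sig)):
            raise ValueError("non-finite inputs")
        r = obs - sig
        return -0.5 * (r / self.sigma) ** 2 - np.log(self.sigma) - 0.5 * _LOG2PI

    def dloglik_dsignal(self, observation, signal):
        obs = np.asarray(observation, dtype=np.float64)
        raw = np.asarray(signal, dtype=np.float64)
        sig = self._clamp(raw)
        return (obs - sig) / self.sigma**2 * self._inside(raw)

    def to_dict(self):
        return {
            "kind": "gaussian",
            "sigma": float(self.sigma),
            "signal_range": [float(v) for v in self.signal_range],
        }


@dataclass
class PoissonGaussianNoiseModel(NoiseModel):
    """Gaussian approximation with variance sigma^2 + scale * signal."""

    gaussian_sigma: float
    poisson_scale: float
    signal_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        if self.gaussian_sigma < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.gaussian_sigma == 0 and self.poisson_scale == 0:
            raise ValueError("model is degenerate (no noise)")

    def _var(self, sig):
        v = self.gaussian_sigma**2 + self.poisson_scale * np.maximum(sig, 0.0)
        return np.maximum(v, 1e-12)

    def loglikelihood(self, observation, signal):
        obs = np.asarray(observation, dtype=np.float64)
        sig = self._clamp(np.asarray(signal, dtype=np.float64))
        if np.any(~np.isfinite(obs)) or np.any(~np.isfinite(sig)):
            raise ValueError("non-finite inputs")
        v = self._var(sig)
        return -0.5 * ((obs - sig) ** 2 / v + np.log(v) + _LOG2PI)

    def dloglik_dsignal(self, observation, signal):
        obs = np.asarray(observation, dtype=np.float64)
        raw = np.asarray(signal, dtype=np.float64)
        sig = self._clamp(raw)
        v = self._var(sig)
        r = obs - sig
        dv = self.poisson_scale
        return (r / v + 0.5 * dv * (r**2 / v**2 - 1.0 / v)) * self._inside(raw)

    def to_dict(self):
        return {
            "kind": "poisson_gaussian",
            "gaussian_sigma": float(self.gaussian_sigma),
            "poisson_scale": float(self.poisson_scale),
            "signal_range": [float(v) for v in self.signal_range],
        }


# --------------------------------------------------------------------------- #

class SignalDependentGMM(NoiseModel):
    """Mixture over the observation conditioned on the clean signal.

    Component m at normalized signal t in [0, 1]:
        weight  pi_m = softmax_m(a_m(t))
        mean    mu_m = signal + o_m(t)
        std     sigma_m = min_std + exp(l_m(t))
    with a, o, l polynomials (highest degree first, np.polyval convention).
    """

    def __init__(self, weight_coeffs, offset_coeffs, logstd_coeffs,
                 signal_range, min_std=1e-3):
        self.weight_coeffs = np.asarray(weight_coeffs, dtype=np.float64)
        self.offset_coeffs = np.asarray(offset_coeffs, dtype=np.float64)
        self.logstd_coeffs = np.asarray(logstd_coeffs, dtype=np.float64)
        if not (self.weight_coeffs.shape == self.offset_coeffs.shape
                == self.logstd_coeffs.shape):
            raise ValueError("coefficient arrays must share shape (m, degree+1)")
        self.signal_range = (float(signal_range[0]), float(signal_range[1]))
        self.min_std = float(min_std)

    @property
    def n_components(self):
        return self.weight_coeffs.shape[0]

    def _t(self, sig):
        lo, hi = self.signal_range
        return (sig - lo) / max(hi - lo, 1e-12)

    def _params(self, sig):
        t = self._t(sig)
        a = np.stack([np.polyval(c, t) for c in self.weight_coeffs])
        a -= a.max(axis=0, keepdims=True)
        pi = np.exp(a)
        pi /= pi.sum(axis=0, keepdims=True)
        off = np.stack([np.polyval(c, t) for c in self.offset_coeffs])
        std = self.min_std + np.exp(
            np.stack([np.polyval(c, t) for c in self.logstd_coeffs])
        )
        return pi, off, std, t

    def component_table(self, signals):
        """(weights, means, stds) per component at the given signal levels."""
        sig = self._clamp(np.asarray(signals, dtype=np.float64))
        pi, off, std, _ = self._params(sig)
        return pi, sig + off, std

    def _logp_terms(self, obs, sig):
        pi, off, std, t = self._params(sig)
        z = (obs - sig - off) / std
        logn = -0.5 * z * z - np.log(std) - 0.5 * _LOG2PI
        logw = np.log(np.maximum(pi, 1e-300)) + logn
        m = logw.max(axis=0)
        logp = m + np.log(np.exp(logw - m).sum(axis=0))
        resp = np.exp(logw - logp)
        return logp, resp, pi, off, std, z, t

    def loglikelihood(self, observation, signal):
        obs = np.asarray(observation, dtype=np.float64)
        sig = self._clamp(np.asarray(signal, dtype=np.float64))
        if np.any(~np.isfinite(obs)) or np.any(~np.isfinite(sig)):
            raise ValueError("non-finite inputs")
        return self._logp_terms(obs, sig)[0]

    def dloglik_dsignal(self, observation, signal):
        obs = np.asarray(observation, dtype=np.float64)
        raw = np.asarray(signal, dtype=np.float64)
        sig = self._clamp(raw)
        _, resp, pi, off, std, z, t = self._logp_terms(obs, sig)
        lo, hi = self.signal_range
        dt = 1.0 / max(hi - lo, 1e-12)
        dmu = 1.0 + np.stack(
            [np.polyval(np.polyder(c) if len(c) > 1 else [0.0], t)
             for c in self.offset_coeffs]
        ) * dt
        dl = np.stack(
            [np.polyval(np.polyder(c) if len(c) > 1 else [0.0], t)
             for c in self.logstd_coeffs]
        ) * dt
        da = np.stack(
            [np.polyval(np.polyder(c) if len(c) > 1 else [0.0], t)
             for c in self.weight_coeffs]
        ) * dt
        dstd = (std - self.min_std) * dl
        term = resp * (z / std * dmu + (z * z - 1.0) / std * dstd)
        wterm = (resp - pi) * da
        return (term.sum(axis=0) + wterm.sum(axis=0)) * self._inside(raw)

    def to_dict(self):
        return {
            "kind": "gmm",
            "weight_coeffs": self.weight_coeffs.tolist(),
            "offset_coeffs": self.offset_coeffs.tolist(),
            "logstd_coeffs": self.logstd_coeffs.tolist(),
            "signal_range": [float(v) for v in self.signal_range],
            "min_std": self.min_std,
        }


# --------------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------------- #

def fit_noise_model(pairs, n_components=1, degree=0, max_iter=200, seed=0,
                    max_pixels=2_000_000) -> SignalDependentGMM:
    """Fit a SignalDependentGMM to (clean reference, noisy observation) pairs
    by gradient ascent on the mixture log-likelihood.

    ``pairs`` is a sequence of (signal_image, observation_image) arrays.
    Raises on degenerate input (constant reference or essentially noiseless
    residuals — the std lower bound would bind).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    sig = np.concatenate([np.asarray(s, np.float64).ravel() for s, _ in pairs])
    obs = np.concatenate([np.asarray(o, np.float64).ravel() for _, o in pairs])
    if sig.shape != obs.shape:
        raise ValueError("signal/observation size mismatch")
    if sig.std() < 1e-12:
        raise ValueError("degenerate calibration pairs: constant reference")
    rng = np.random.default_rng(seed)
    if sig.size > max_pixels:
        idx = rng.choice(sig.size, max_pixels, replace=False)
        sig, obs = sig[idx], obs[idx]

    lo, hi = np.percentile(sig, [0.1, 99.9])
    if hi <= lo:
        raise ValueError("degenerate signal range")
    resid = obs - sig
    resid_std = resid.std()
    data_scale = hi - lo
    min_std = 1e-4 * data_scale
    if resid_std <= 2 * min_std:
        raise ValueError(
            "residuals are essentially noiseless; std lower bound would bind"
        )

    m, p = n_components, degree + 1
    # seeded init: stds log-spaced around the residual std, offsets ~0
    logstd0 = np.log(resid_std * np.geomspace(0.5, 2.0, m))
    x0 = np.zeros(3 * m * p)
    x0[2 * m * p::p] = 0.0
    for j in range(m):
        x0[2 * m * p + j * p + (p - 1)] = logstd0[j]
        x0[m * p + j * p + (p - 1)] = rng.normal(0, 0.05 * resid_std)

    def unpack(x):
        w = x[: m * p].reshape(m, p)
        o = x[m * p : 2 * m * p].reshape(m, p)
        l = x[2 * m * p :].reshape(m, p)
        return w, o, l

    tnorm = (sig - lo) / data_scale
    tpow = np.stack([tnorm ** (p - 1 - j) for j in range(p)])  # (p, n)

    def nll_and_grad(x):
        w, o, l = unpack(x)
        model = SignalDependentGMM(w, o, l, (lo, hi), min_std)
        logp, resp, pi, off, std, z, _ = model._logp_terms(obs, sig)
        nll = -logp.mean()
        n = sig.size
        gw = -((resp - pi)[:, None, :] * tpow[None]).mean(axis=2) * n / n
        gmu = -((resp * z / std)[:, None, :] * tpow[None]).mean(axis=2)
        gl = -((resp * (z * z - 1.0) * (std - min_std) / std)[:, None, :]
               * tpow[None]).mean(axis=2)
        return nll, np.concatenate([gw.ravel(), gmu.ravel(), gl.ravel()])

    res = minimize(nll_and_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    w, o, l = unpack(res.x)
    model = SignalDependentGMM(w, o, l, (lo, hi), min_std)
    _, _, stds = model.component_table(np.linspace(lo, hi, 5))
    if np.any(stds <= 2 * min_std):
        raise ValueError("fit rejected: component std collapsed to lower bound")
    return model
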