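"""Loss algebra: KL closed forms and cropping, likelihood branches, and the
weighted combined objective."""

import numpy as np
import pytest

from chansplit.losses import (
    LOG2PI,
    LossConfig,
    combined_loss,
    gaussian_branch_nll,
    kl_elementwise,
    kl_loss_3d,
    kl_loss_cropped,
    kl_per_level,
    noise_model_branch_nll,
    total_kl,
)
from chansplit.nn import Tensor
from chansplit.noise_model import GaussianNoiseModel
from chansplit.vse import LevelLatents, NormStats


def make_latents(rng, shape=(2, 3, 8, 8)):
    return LevelLatents(
        q_mu=Tensor(rng.normal(size=shape)),
        q_logvar=Tensor(rng.normal(size=shape) * 0.3),
        p_mu=Tensor(rng.normal(size=shape)),
        p_logvar=Tensor(rng.normal(size=shape) * 0.3),
    )


class TestKLElementwise:
    def test_identical_distributions_zero(self, rng):
        mu, lv = Tensor(rng.normal(size=(1, 2, 4, 4))), Tensor(rng.normal(size=(1, 2, 4, 4)))
        kl = kl_elementwise(LevelLatents(mu, lv, mu, lv))
        np.testing.assert_allclose(kl.data, 0.0, atol=1e-7)

    def test_unit_shift_closed_form(self):
        one = Tensor(np.ones((1, 1, 2, 2)))
        zero = Tensor(np.zeros((1, 1, 2, 2)))
        kl = kl_elementwise(LevelLatents(one, zero, zero, zero))
        np.testing.assert_allclose(kl.data, 0.5, atol=1e-7)

    def test_matches_monte_carlo(self, rng):
        lat = make_latents(rng, shape=(1, 1, 2, 2))
        kl = kl_elementwise(lat).data
        n = 100_000
        q_mu, q_sd = lat.q_mu.data, np.exp(0.5 * lat.q_logvar.data)
        p_mu, p_sd = lat.p_mu.data, np.exp(0.5 * lat.p_logvar.data)
        z = q_mu[None] + q_sd[None] * rng.standard_normal((n,) + q_mu.shape)
        logq = -0.5 * ((z - q_mu) / q_sd) ** 2 - np.log(q_sd) - 0.5 * LOG2PI
        logp = -0.5 * ((z - p_mu) / p_sd) ** 2 - np.log(p_sd) - 0.5 * LOG2PI
        mc = (logq - logp).mean(axis=0)
        se = (logq - logp).std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(mc - kl) < 3.5 * se + 1e-4)

    def test_shape_mismatch_raises(self, rng):
        lat = LevelLatents(
            Tensor(rng.normal(size=(1, 1, 4, 4))), Tensor(rng.normal(size=(1, 1, 4, 4))),
            Tensor(rng.normal(size=(1, 1, 2, 2))), Tensor(rng.normal(size=(1, 1, 2, 2))))
        with pytest.raises(ValueError):
            kl_elementwise(lat)


class TestKLCropped:
    def test_identity_crop_equals_plain_sum(self, rng):
        lat = make_latents(rng)
        kl = kl_per_level([lat])[0]
        full = kl_loss_cropped(kl, (8, 8), alpha=1.0)
        plain = kl.data.sum() / kl.shape[0]
        assert float(full.data) == pytest.approx(plain, rel=1e-6)

    def test_center_block_enumeration_oracle(self):
        data = np.arange(2 * 1 * 6 * 6, dtype=np.float32).reshape(2, 1, 6, 6)
        kl = Tensor(data)
        got = float(kl_loss_cropped(kl, (2, 2), alpha=1.0).data)
        # hand-enumerated centre 2x2 (rows/cols 2..3), per element, batch mean
        expect = sum(data[n, 0, i, j] for n in range(2)
                     for i in (2, 3) for j in (2, 3)) / 2
        assert got == pytest.approx(expect, rel=1e-6)

    def test_alpha_linearity(self, rng):
        lat = make_latents(rng)
        kl = kl_per_level([lat])[0]
        a = float(kl_loss_cropped(kl, (4, 4), alpha=1.0).data)
        b = float(kl_loss_cropped(kl, (4, 4), alpha=2.0).data)
        assert b == pytest.approx(2 * a, rel=1e-6)

    def test_default_alpha_is_per_pixel(self, rng):
        lat = make_latents(rng)
        kl = kl_per_level([lat])[0]
        auto = float(kl_loss_cropped(kl, (4, 4)).data)
        manual = float(kl_loss_cropped(kl, (4, 4), alpha=1.0 / 16).data)
        assert auto == pytest.approx(manual, rel=1e-6)

    def test_target_larger_raises(self, rng):
        kl = kl_per_level([make_latents(rng)])[0]
        with pytest.raises(ValueError):
            kl_loss_cropped(kl, (16, 16), alpha=1.0)


class TestKL3D:
    def test_z1_equals_2d_path(self, rng):
        kl4 = Tensor(rng.uniform(size=(2, 3, 1, 8, 8)).astype(np.float32))
        kl2 = Tensor(kl4.data[:, :, 0])
        a = float(kl_loss_3d(kl4, (4, 4), alpha=1.0).data)
        b = float(kl_loss_cropped(kl2, (4, 4), alpha=1.0).data)
        assert a == pytest.approx(b, rel=1e-6)

    @pytest.mark.parametrize("z", [1, 4, 16])
    def test_invariant_to_z_replication(self, rng, z):
        base = rng.uniform(size=(2, 3, 8, 8)).astype(np.float32)
        kl4 = Tensor(np.repeat(base[:, :, None], z, axis=2))
        val = float(kl_loss_3d(kl4, (4, 4), alpha=1.0).data)
        ref = float(kl_loss_cropped(Tensor(base), (4, 4), alpha=1.0).data)
        assert val == pytest.approx(ref, rel=1e-5)

    def test_random_tensor_brute_force_oracle(self, rng):
        kl4 = Tensor(rng.uniform(size=(3, 2, 5, 6, 6)).astype(np.float32))
        got = float(kl_loss_3d(kl4, (4, 4), alpha=1.0).data)
        # brute force: mean over z, centre-crop rows/cols 1..4, sum, batch mean
        man = kl4.data.mean(axis=2)[:, :, 1:5, 1:5].sum() / 3
        assert got == pytest.approx(man, rel=1e-5)


class TestGaussianBranch:
    def test_perfect_prediction_unit_variance(self, rng):
        t = rng.normal(size=(2, 1, 4, 4)).astype(np.float32)
        nll = gaussian_branch_nll(Tensor(t), t, None, fixed_sigma=1.0)
        assert float(nll.data) == pytest.approx(0.5 * LOG2PI * 16, rel=1e-5)

    def test_residual_doubling_quadruples_quadratic(self, rng):
        t = np.zeros((1, 1, 4, 4), np.float32)
        r = rng.normal(size=t.shape).astype(np.float32)
        base = 0.5 * LOG2PI * 16
        n1 = float(gaussian_branch_nll(Tensor(r), t, None).data) - base
        n2 = float(gaussian_branch_nll(Tensor(2 * r), t, None).data) - base
        assert n2 == pytest.approx(4 * n1, rel=1e-4)

    def test_learned_variance_tracks_heteroscedastic_noise(self, rng):
        # directly optimize per-pixel logvar for fixed residuals; the optimum
        # is log(residual^2): check recovery by gradient descent
        from chansplit.nn import Adamax
        sd = rng.uniform(0.5, 3.0, size=(1, 1, 16, 16)).astype(np.float32)
        resid = (sd * rng.standard_normal((200, 1, 16, 16))).astype(np.float32)
        lv = Tensor(np.zeros((1, 1, 16, 16)), requires_grad=True)
        opt = Adamax([lv], lr=0.05)
        mean = Tensor(np.zeros((200, 1, 16, 16)))
        for _ in range(200):
            opt.zero_grad()
            nll = gaussian_branch_nll(mean, resid, logvar=lv + 0.0)
            # broadcast logvar over batch via addition of zero tensor
            nll.backward()
            opt.step()
        fitted_var = np.exp(lv.data[0, 0])
        r = np.corrcoef(fitted_var.ravel(), (sd[0, 0] ** 2).ravel())[0, 1]
        assert r > 0.9

    def test_non_finite_prediction_rejected(self):
        bad = Tensor(np.full((1, 1, 2, 2), np.nan))
        with pytest.raises(FloatingPointError):
            gaussian_branch_nll(bad, np.zeros((1, 1, 2, 2)))


class TestNoiseModelBranch:
    def test_gaussian_model_equals_fixed_variance_up_to_constant(self, rng):
        sigma = 3.0
        t = rng.normal(size=(2, 2, 4, 4)).astype(np.float32) * 10
        model = GaussianNoiseModel(sigma)
        for trial in range(3):
            pred = Tensor(rng.normal(size=t.shape).astype(np.float32) * 10)
            a = float(noise_model_branch_nll(pred, t, model).data)
            b = float(gaussian_branch_nll(pred, t, None, fixed_sigma=sigma).data)
            assert a == pytest.approx(b, rel=1e-4)

    def test_missing_model_raises(self, rng):
        pred = Tensor(rng.normal(size=(1, 1, 2, 2)))
        with pytest.raises(ValueError):
            noise_model_branch_nll(pred, np.zeros((1, 1, 2, 2)), None)

    def test_gradient_direction_reduces_nll(self, rng):
        model = GaussianNoiseModel(2.0)
        t = rng.normal(size=(1, 1, 8, 8)).astype(np.float32) * 5
        pred = Tensor(np.zeros_like(t), requires_grad=True)
        nll = noise_model_branch_nll(pred, t, model)
        nll.backward()
        stepped = Tensor(pred.data - 0.01 * pred.grad)
        nll2 = noise_model_branch_nll(stepped, t, model)
        assert float(nll2.data) < float(nll.data)


class TestCombined:
    def _setup(self, rng, w=0.9):
        pred = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        tn = rng.normal(size=(2, 2, 8, 8)).astype(np.float32)
        traw = (tn * 5 + 50).astype(np.float32)
        lat = [make_latents(rng, (2, 3, 8, 8)), make_latents(rng, (2, 3, 8, 8))]
        model = GaussianNoiseModel(5.0)
        norm = NormStats(target_mean=np.full(2, 50.0, np.float32),
                         target_std=np.full(2, 5.0, np.float32))
        shapes = [(8, 8), (4, 4)]
        return pred, tn, traw, lat, model, norm, shapes

    def test_affine_in_w(self, rng):
        pred, tn, traw, lat, model, norm, shapes = self._setup(rng)
        vals = {}
        for w in (0.0, 0.25, 0.5, 1.0):
            loss, _ = combined_loss(pred, tn, lat, model,
                                    LossConfig(w=w), shapes, norm=norm,
                                    target_raw=traw, k_out=2)
            vals[w] = float(loss.data)
        # affine fit through w=0 and w=1 predicts the interior points
        for w in (0.25, 0.5):
            lin = vals[0.0] + w * (vals[1.0] - vals[0.0])
            assert vals[w] == pytest.approx(lin, rel=1e-5)

    def test_w_extremes_select_pure_branches(self, rng):
        pred, tn, traw, lat, model, norm, shapes = self._setup(rng)
        cfg0 = LossConfig(w=0.0)
        loss0, bd0 = combined_loss(pred, tn, lat, model, cfg0, shapes,
                                   norm=norm, target_raw=traw, k_out=2)
        kl = float(total_kl(lat, shapes, cfg0)[0].data)
        mu_branch = float(gaussian_branch_nll(pred[:, :2], tn, pred[:, 2:]).data) + kl
        assert float(loss0.data) == pytest.approx(mu_branch, rel=1e-5)

        loss1, bd1 = combined_loss(pred, tn, lat, model, LossConfig(w=1.0),
                                   shapes, norm=norm, target_raw=traw, k_out=2)
        mean_raw = pred.data[:, :2] * 5.0 + 50.0
        den = float(noise_model_branch_nll(Tensor(mean_raw), traw, model).data) + kl
        assert float(loss1.data) == pytest.approx(den, rel=1e-5)

    def test_default_w(self):
        assert LossConfig().w == 0.9

    def test_branch_equivalence_gaussian_noise(self, rng):
        # with a Gaussian noise model, identity normalization and matched
        # fixed variance, the two branches differ by exactly zero
        pred, tn, _, lat, _, _, shapes = self._setup(rng)
        model = GaussianNoiseModel(4.0)
        norm = NormStats(target_mean=np.zeros(2, np.float32),
                         target_std=np.ones(2, np.float32))
        cfg = LossConfig(w=0.5, likelihood_variance_mode="fixed", fixed_sigma=4.0)
        loss, bd = combined_loss(pred, tn, lat, model, cfg, shapes,
                                 norm=norm, target_raw=tn, k_out=2)
        assert bd["nll_denoise"] == pytest.approx(bd["nll_gaussian"], rel=1e-5)

    def test_smoke_finite_and_differentiable(self):
        # loss finite with nonzero gradients across many random draws
        for seed in range(30):
            r = np.random.default_rng(seed)
            pred = Tensor(r.normal(size=(1, 4, 8, 8)).astype(np.float32),
                          requires_grad=True)
            tn = r.normal(size=(1, 2, 8, 8)).astype(np.float32)
            lat = [make_latents(r, (1, 2, 8, 8))]
            loss, bd = combined_loss(pred, tn, lat, GaussianNoiseModel(1.0),
                                     LossConfig(), [(4, 4)],
                                     target_raw=tn, k_out=2)
            assert np.isfinite(loss.data)
            loss.backward()
            assert pred.grad is not None and np.all(np.isfinite(pred.grad))
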