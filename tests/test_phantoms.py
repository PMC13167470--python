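"""Phantom generators, mixing, training-mode assembly and noise."""

import numpy as np
import pytest
from skimage.measure import label

from chansplit.phantoms import (
    ChannelStack,
    MixTask,
    NoiseSpec,
    apply_noise,
    assemble_mode_I,
    assemble_mode_II,
    assemble_mode_IIb,
    assemble_mode_III,
    generate_colocalized_pair,
    generate_structure_channel,
    make_mode_III_stack,
    make_scaled_copy_task,
    mix_channels,
    SCALED_COPY_FACTORS,
)


class TestGenerators:
    def test_zero_density_gives_empty_image(self):
        s = generate_structure_channel("puncta", (128, 128), 0.0, seed=1)
        assert np.all(s.data == 0)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError, match="unknown structure kind"):
            generate_structure_channel("stripes", (64, 64), 1e-4, seed=0)

    def test_too_small_shape_raises(self):
        with pytest.raises(ValueError, match=">= 32"):
            generate_structure_channel("puncta", (16, 64), 1e-4, seed=0)

    def test_seed_determinism(self):
        a = generate_structure_channel("rings", (64, 64), 5e-4, seed=7)
        b = generate_structure_channel("rings", (64, 64), 5e-4, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_puncta_count_matches_density(self):
        # independent connected-component oracle: spot count ~ Poisson(d*area)
        d, area = 3e-4, 256 * 256
        s = generate_structure_channel("puncta", (256, 256), d, seed=7)
        n_cc = label(s.data[0] > 10.0).max()
        lam = d * area
        assert abs(n_cc - lam) <= 3 * np.sqrt(lam) + 2

    @pytest.mark.parametrize("kind", ["filaments", "blobs", "puncta", "rings"])
    def test_clean_phantoms_nonnegative(self, kind):
        s = generate_structure_channel(kind, (64, 64), 1e-3, seed=3)
        assert np.all(s.data >= 0) and np.all(np.isfinite(s.data))


class TestMixing:
    def test_identity_single_channel(self, rng):
        s = ChannelStack(rng.uniform(size=(1, 32, 32)).astype(np.float32))
        np.testing.assert_array_equal(mix_channels(s, [1.0]), s.data[0])

    def test_equal_weights_is_plain_sum(self, rng):
        d = rng.uniform(size=(2, 16, 16)).astype(np.float32)
        s = ChannelStack(d)
        np.testing.assert_allclose(mix_channels(s, [1.0, 1.0]), d[0] + d[1],
                                   rtol=1e-6)

    def test_table_skew_66_33(self, rng):
        # the high-skew 66:33 family corresponds to weights (2, 1)
        d = rng.uniform(size=(2, 8, 8)).astype(np.float32)
        out = mix_channels(ChannelStack(d), [2.0, 1.0])
        np.testing.assert_allclose(out, 2 * d[0] + d[1], rtol=1e-6)

    def test_weight_count_mismatch(self, rng):
        s = ChannelStack(rng.uniform(size=(2, 8, 8)).astype(np.float32))
        with pytest.raises(ValueError):
            mix_channels(s, [1.0])


class TestModeI:
    def test_input_is_exact_sum(self, bars_and_spots):
        inp, tgt = assemble_mode_I(bars_and_spots, (10, 20), (64, 64))
        np.testing.assert_array_equal(inp, tgt.sum(axis=0))

    def test_residual_zero(self, bars_and_spots):
        inp, tgt = assemble_mode_I(bars_and_spots, (0, 0), (64, 64))
        assert np.all(tgt.sum(axis=0) - inp == 0)

    def test_correlation_preserved(self):
        pair = generate_colocalized_pair((256, 256), 1e-3, rho=0.6, seed=4)
        r_src = np.corrcoef(pair.data[0].ravel(), pair.data[1].ravel())[0, 1]
        _, tgt = assemble_mode_I(pair, (0, 0), (256, 256))
        r_tgt = np.corrcoef(tgt[0].ravel(), tgt[1].ravel())[0, 1]
        assert r_tgt == pytest.approx(r_src, abs=1e-6)
        assert r_src > 0.3  # phantom actually is colocalized


class TestModeII:
    def _sources(self):
        pair = generate_colocalized_pair((256, 256), 1e-3, rho=0.6, seed=4)
        return [ChannelStack(pair.data[0][None]), ChannelStack(pair.data[1][None])]

    def test_destroys_cross_channel_correlation(self):
        srcs = self._sources()
        vals_a, vals_b = [], []
        for i in range(40):
            _, tgt = assemble_mode_II(srcs, (64, 64), seed=100 + i)
            vals_a.append(tgt[0].ravel())
            vals_b.append(tgt[1].ravel())
        r = np.corrcoef(np.concatenate(vals_a), np.concatenate(vals_b))[0, 1]
        assert abs(r) < 0.05

    def test_seed_reproducible(self):
        srcs = self._sources()
        a = assemble_mode_II(srcs, (32, 32), seed=9)
        b = assemble_mode_II(srcs, (32, 32), seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_sum_definition(self):
        srcs = self._sources()
        inp, tgt = assemble_mode_II(srcs, (32, 32), seed=1)
        np.testing.assert_allclose(inp, tgt.sum(axis=0), rtol=1e-6)


class TestModeIIb:
    def test_single_pair_exact_sum(self, rng):
        a = rng.uniform(size=(100, 100)).astype(np.float32)
        b = rng.uniform(size=(100, 100)).astype(np.float32)
        inp, tgt, _ = assemble_mode_IIb([a], [b], seed=0)
        np.testing.assert_allclose(inp, a + b, rtol=1e-6)

    def test_empty_crop_list_raises(self, rng):
        a = rng.uniform(size=(100, 100)).astype(np.float32)
        with pytest.raises(ValueError):
            assemble_mode_IIb([a], [], seed=0)

    def test_large_collection_scale_accepted(self, rng):
        # the motivating collection: 82 + 48 small regions, LC disabled
        crops_a = [rng.uniform(size=(100, 100)).astype(np.float32) for _ in range(82)]
        crops_b = [rng.uniform(size=(100, 100)).astype(np.float32) for _ in range(48)]
        inp, tgt, idx = assemble_mode_IIb(crops_a, crops_b, seed=1)
        assert inp.shape == (100, 100)
        assert 0 <= idx[0] < 82 and 0 <= idx[1] < 48

    def test_pairing_uniform_over_crops(self, rng):
        crops_a = [np.full((4, 4), i, np.float32) for i in range(3)]
        crops_b = [np.full((4, 4), 10.0 * i, np.float32) for i in range(3)]
        counts = np.zeros((3, 3))
        n = 3000
        for s in range(n):
            _, _, (ia, ib) = assemble_mode_IIb(crops_a, crops_b, seed=s)
            counts[ia, ib] += 1
        expected = n / 9
        # frequency oracle: chi-square against uniform pair distribution
        chi2 = ((counts - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.999, df=8)


class TestModeIII:
    def test_input_independent_noise_unbiased(self, bars_and_spots):
        clean = bars_and_spots
        spec = NoiseSpec(gaussian_sigma=20.0, poisson_scale=0.0, seed=0)
        # mean over many fresh acquisitions approaches the clean sum
        acc = np.zeros(clean.spatial_shape, np.float32)
        reps = 60
        for i in range(reps):
            stack = make_mode_III_stack(
                clean, NoiseSpec(20.0, 0.0, seed=1000 + i))
            inp, tgt = assemble_mode_III(stack, (0, 0), (64, 64))
            acc[:64, :64] += inp
            assert not np.array_equal(inp, tgt.sum(axis=0))
        mean_inp = acc[:64, :64] / reps
        clean_sum = clean.data.sum(axis=0)[:64, :64]
        assert np.abs(mean_inp - clean_sum).mean() < 4 * 20.0 / np.sqrt(reps)

    def test_zero_noise_degenerates_to_mode_I(self, bars_and_spots):
        stack = make_mode_III_stack(bars_and_spots, NoiseSpec(0.0, 0.0, seed=0))
        inp, tgt = assemble_mode_III(stack, (5, 5), (32, 32))
        np.testing.assert_allclose(inp, tgt.sum(axis=0), rtol=1e-5)

    def test_missing_superimposed_channel_raises(self, rng):
        s = ChannelStack(rng.uniform(size=(1, 32, 32)).astype(np.float32))
        with pytest.raises(ValueError):
            assemble_mode_III(s)


class TestScaledCopy:
    def test_supported_factors(self):
        assert SCALED_COPY_FACTORS == (1.032, 1.063, 1.125, 1.25, 1.5, 2.0)

    def test_s_below_one_raises(self, bars_and_spots):
        src = ChannelStack(bars_and_spots.data[:1])
        with pytest.raises(ValueError):
            make_scaled_copy_task(src, 0.5, (64, 64), seed=0)

    def test_s2_intensity_ratio(self):
        src = generate_structure_channel("filaments", (512, 512), 1e-3, seed=2)
        means = []
        for i in range(200):
            stack = make_scaled_copy_task(src, 2.0, (64, 64), seed=i)
            means.append(stack.data.mean(axis=(1, 2)))
        m = np.mean(means, axis=0)
        assert m[1] / m[0] == pytest.approx(2.0, rel=0.15)

    def test_s1_identical_distribution(self):
        src = generate_structure_channel("filaments", (512, 512), 1e-3, seed=2)
        means = []
        for i in range(200):
            stack = make_scaled_copy_task(src, 1.0, (64, 64), seed=i)
            means.append(stack.data.mean(axis=(1, 2)))
        m = np.mean(means, axis=0)
        assert m[1] / m[0] == pytest.approx(1.0, rel=0.1)


class TestNoise:
    def test_identity_when_disabled(self, rng):
        img = rng.uniform(size=(32, 32)).astype(np.float32)
        out = apply_noise(img, NoiseSpec(0.0, 0.0, seed=0))
        np.testing.assert_array_equal(out, img)

    def test_gaussian_sigma_500(self):
        img = np.full((600, 600), 1000.0, np.float32)
        out = apply_noise(img, NoiseSpec(500.0, 0.0, seed=3))
        sd = out.std()
        n = img.size
        assert abs(sd - 500.0) < 3 * 500.0 / np.sqrt(2 * n) + 5.0

    def test_poisson_variance_identity(self):
        v, scale = 200.0, 4.0
        img = np.full((500, 500), v, np.float32)
        out = apply_noise(img, NoiseSpec(0.0, scale, seed=3))
        # var = scale^2 * (v / scale) = v * scale
        assert out.var() == pytest.approx(v * scale, rel=0.05)
        assert out.mean() == pytest.approx(v, rel=0.01)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(gaussian_sigma=-1.0)

    def test_seeded(self, rng):
        img = rng.uniform(size=(16, 16)).astype(np.float32) * 100
        a = apply_noise(img, NoiseSpec(5.0, 2.0, seed=9))
        b = apply_noise(img, NoiseSpec(5.0, 2.0, seed=9))
        np.testing.assert_array_equal(a, b)


class TestTypes:
    def test_mixtask_validation(self):
        with pytest.raises(ValueError):
            MixTask(k=2, weights=[1.0])
        with pytest.raises(ValueError):
            MixTask(k=3, weights=[1, 1, 1], similarity_scale=1.5)
        with pytest.raises(ValueError):
            MixTask(k=5, weights=[1] * 5)

    def test_channelstack_validation(self, rng):
        with pytest.raises(ValueError):
            ChannelStack(np.array([[1.0, np.inf]]))
        with pytest.raises(ValueError):
            ChannelStack(rng.uniform(size=(2, 8, 8)), channel_names=["a"])
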