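"""Quality metrics: hand-computed cases, closed forms, independent oracles."""

import numpy as np
import pytest

from mcdn.metrics import (
    MetricsReport,
    PSNRParams,
    SSIMParams,
    cross_section_profile,
    delta_snr,
    mae,
    make_report,
    mse,
    photon_multiplier,
    psnr,
    snr_map,
    ssim3d,
)


class TestMseMae:
    def test_identical_volumes_are_zero(self, rng):
        x = rng.random((4, 4, 4))
        assert mse(x, x) == 0.0
        assert mae(x, x) == 0.0

    def test_constant_difference(self):
        x = np.zeros((3, 3, 3))
        assert mse(x, x + 2.0) == pytest.approx(4.0)
        assert mae(x, x + 2.0) == pytest.approx(2.0)

    def test_hand_computed_2x2x2(self):
        x = np.arange(8, dtype=float).reshape(2, 2, 2)
        y = x.copy()
        y[0, 0, 0] += 3.0
        y[1, 1, 1] -= 1.0
        assert mse(x, y) == pytest.approx((9.0 + 1.0) / 8.0)
        assert mae(x, y) == pytest.approx((3.0 + 1.0) / 8.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestSsim3d:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((12, 12, 12)) * 40
        assert ssim3d(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self, rng):
        x, y = rng.random((10, 10, 10)), rng.random((10, 10, 10))
        assert ssim3d(x, y) == pytest.approx(ssim3d(y, x), abs=1e-12)

    def test_constant_volumes_closed_form(self):
        # zero variances collapse the structure term to C2/C2 = 1
        a, b = 3.0, 7.0
        params = SSIMParams()
        expected = (2 * a * b + params.c1) / (a * a + b * b + params.c1)
        got = ssim3d(np.full((5, 5, 5), a), np.full((5, 5, 5), b), params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_direct_windowed_computation(self, rng):
        # independent oracle: explicit separable Gaussian window + direct sums
        sigma, trunc = 1.5, 2.0
        params = SSIMParams(gaussian_sigma=sigma, truncate=trunc)
        radius = int(trunc * sigma + 0.5)
        t = np.arange(-radius, radius + 1)
        k1 = np.exp(-t * t / (2 * sigma * sigma))
        k1 /= k1.sum()
        kern = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]

        def smooth(a):
            ap = np.pad(a, radius, mode="symmetric")  # edge-repeating reflection
            from numpy.lib.stride_tricks import sliding_window_view

            win = sliding_window_view(ap, kern.shape)
            return np.einsum("ijkabc,abc->ijk", win, kern)

        x = rng.random((9, 9, 9)) * 40
        y = x + rng.normal(0, 2, size=x.shape)
        ux, uy = smooth(x), smooth(y)
        vx, vy = smooth(x * x) - ux ** 2, smooth(y * y) - uy ** 2
        cov = smooth(x * y) - ux * uy
        c1, c2 = params.c1, params.c2
        expected = np.mean(((2 * ux * uy + c1) * (2 * cov + c2))
                           / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))
        assert ssim3d(x, y, params) == pytest.approx(expected, rel=1e-10)

    def test_bounded_above_by_one(self, rng):
        for _ in range(5):
            x = rng.random((8, 8, 8)) * 40
            y = rng.random((8, 8, 8)) * 40
            assert ssim3d(x, y) <= 1.0


class TestPsnr:
    def test_constant_difference_reference_points(self):
        x = np.zeros((4, 4, 4))
        assert psnr(x, x + 40.0) == pytest.approx(0.0, abs=1e-12)
        assert psnr(x, x + 4.0) == pytest.approx(20.0, abs=1e-12)

    def test_duality_with_mse(self, rng):
        x, y = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        expected = 20 * np.log10(40.0) - 10 * np.log10(mse(x, y))
        assert psnr(x, y) == pytest.approx(expected, rel=1e-9)

    def test_identical_volumes_infinite(self, rng):
        x = rng.random((4, 4, 4))
        assert psnr(x, x) == np.inf

    def test_custom_peak(self):
        x = np.zeros((3, 3, 3))
        assert psnr(x, x + 1.0, PSNRParams(i_max=10.0)) == pytest.approx(20.0)


class TestSnrMap:
    def test_two_value_hand_case(self):
        stack = [np.full((2, 2, 2), 9.0), np.full((2, 2, 2), 11.0)]
        m = snr_map(stack)
        assert m.valid.all()
        np.testing.assert_allclose(m.values, 20.0)  # mu=10, population sigma=1

    def test_identical_repetitions_have_no_valid_voxels(self):
        stack = [np.ones((3, 3, 3))] * 4
        assert not snr_map(stack).valid.any()

    def test_poisson_stack_matches_shot_noise_theory(self, rng):
        # SNR of Poisson counts: mu/sigma = sqrt(lam) -> 10*log10(lam) dB
        lam = 100.0
        stack = [rng.poisson(lam, size=(6, 6, 6)).astype(float)
                 for _ in range(400)]
        m = snr_map(stack)
        assert m.valid.all()
        assert np.mean(m.values[m.valid]) == pytest.approx(10 * np.log10(lam),
                                                           abs=0.3)

    def test_requires_two_repetitions(self):
        with pytest.raises(ValueError):
            snr_map([np.ones((2, 2, 2))])


class TestDeltaSnr:
    def _map(self, values):
        arr = np.asarray(values, dtype=float)
        from mcdn.metrics import SNRMap

        return SNRMap(values=arr, valid=np.isfinite(arr), n_reps=2)

    def test_no_change_gives_zero_and_empty_effective_region(self):
        m = self._map(np.full((3, 3, 3), 5.0))
        d_all, d_eff = delta_snr(m, m)
        assert d_all == 0.0
        assert np.isnan(d_eff)

    def test_uniform_improvement(self):
        before = self._map(np.zeros((3, 3, 3)))
        after = self._map(np.full((3, 3, 3), 6.0))
        assert delta_snr(before, after) == (6.0, 6.0)

    def test_split_improvement_means(self):
        vals = np.zeros((2, 2, 2))
        after = np.zeros((2, 2, 2))
        after[0] = 10.0  # half improved by 10 dB, half unchanged
        d_all, d_eff = delta_snr(self._map(vals), self._map(after))
        assert d_all == pytest.approx(5.0)
        assert d_eff == pytest.approx(10.0)

    def test_region_mask_restricts_average(self):
        before = self._map(np.zeros((2, 2, 2)))
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = 8.0
        region = np.zeros((2, 2, 2), bool)
        region[0, 0, 0] = True
        d_all, _ = delta_snr(before, self._map(vals), region=region)
        assert d_all == pytest.approx(8.0)

    def test_disjoint_validity_rejected(self):
        a = self._map(np.full((2, 2, 2), np.nan))
        with pytest.raises(ValueError):
            delta_snr(a, a)


class TestPhotonMultiplier:
    def test_reference_points(self):
        assert photon_multiplier(20.0) == pytest.approx(100.0)
        assert photon_multiplier(0.0) == 1.0

    def test_multiplicative_in_db(self, rng):
        a, b = rng.uniform(0, 15, 2)
        assert photon_multiplier(a + b) == pytest.approx(
            photon_multiplier(a) * photon_multiplier(b), rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            photon_multiplier(np.inf)


class TestCrossSectionProfile:
    def test_constant_stack_flat_profile(self):
        stack = [np.full((6, 6, 6), 2.0), np.full((6, 6, 6), 4.0)]
        prof = cross_section_profile(stack, line_axis=1)
        assert len(prof["position"]) == 6
        np.testing.assert_allclose(prof["mean"], 3.0)

    def test_line_outside_volume_rejected(self):
        stack = [np.ones((4, 4, 4))] * 2
        with pytest.raises(ValueError):
            cross_section_profile(stack, 0, fixed_indices=(9, 1))


class TestMetricsReport:
    def test_mf_consistency_enforced(self, rng):
        with pytest.raises(ValueError, match="mf"):
            MetricsReport(mse=0.1, ssim=0.9, psnr=50.0, delta_snr_all=10.0,
                          delta_snr_eff=12.0, mf=5.0)

    def test_make_report_is_self_consistent(self, rng):
        from mcdn.metrics import SNRMap

        x = rng.random((5, 5, 5)) * 10
        y = x + rng.normal(0, 0.1, x.shape)
        vals = rng.uniform(1, 10, (5, 5, 5))
        before = SNRMap(values=vals, valid=np.ones((5, 5, 5), bool), n_reps=10)
        after = SNRMap(values=vals + 3, valid=np.ones((5, 5, 5), bool), n_reps=10)
        rep = make_report(x, y, before, after)
        assert rep.mf == pytest.approx(
            photon_multiplier(rep.delta_snr_all), rel=1e-9)
        assert rep.delta_snr_all == pytest.approx(3.0)
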