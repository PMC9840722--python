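"""LOI processing chain: pixel cleaning, profile difference, denoising,
area integration and the 10-LOI variance measurement."""

import numpy as np
import pytest

from pcctherm import (
    DegenerateProfileError,
    LineProfile,
    VarianceUnavailableError,
    chord_lengths,
    clean_unstable_pixels,
    denoise_profile,
    integrate_lac,
    lac_with_variance,
    magnification,
    measure_scene,
    profile_difference,
    simulate_projection_pair,
)
from pcctherm.extraction import extract_lac_profile

from conftest import ray_march_chords


def profile(values, mask=None, row=0):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask)
    return LineProfile(row, values, mask)


class TestCleanUnstablePixels:
    def test_constant_profile_untouched(self):
        p = clean_unstable_pixels(profile(np.full(100, 1000.0)))
        assert p.n_valid == 100

    def test_gross_outlier_masked(self):
        vals = np.full(1280, 1000.0)
        vals[137] = 1e6
        p = clean_unstable_pixels(profile(vals))
        assert not p.valid_mask[137]
        assert p.n_valid == 1279

    def test_gaussian_mask_fraction_matches_three_sigma(self):
        """For N(mu, sigma) data the 3-SD rule masks ~0.27% of columns."""
        rng = np.random.default_rng(11)
        vals = rng.normal(1000.0, 30.0, size=100_000)
        p = clean_unstable_pixels(profile(vals), k=3.0)
        frac = 1.0 - p.n_valid / vals.size
        assert frac == pytest.approx(0.0027, abs=6e-4)

    def test_too_few_valid_columns_rejected(self):
        with pytest.raises(DegenerateProfileError):
            clean_unstable_pixels(profile(np.ones(5)))


class TestProfileDifference:
    def test_empty_vs_empty_is_zero(self):
        e = profile(np.full(50, 2000.0))
        dp = profile_difference(e, e)
        np.testing.assert_allclose(dp.values[dp.valid_mask], 0.0)

    def test_analytic_log_ratio(self):
        empty = profile(np.full(50, 1000.0))
        filled = profile(np.full(50, 1000.0 * np.exp(-2.0)))
        dp = profile_difference(filled, empty)
        np.testing.assert_allclose(dp.values[dp.valid_mask], 2.0, rtol=1e-12)

    def test_nonpositive_counts_masked_not_fatal(self):
        empty = profile(np.full(20, 1000.0))
        filled_vals = np.full(20, 500.0)
        filled_vals[3] = 0.0
        dp = profile_difference(profile(filled_vals), empty)
        assert not dp.valid_mask[3]
        assert dp.valid_mask.sum() == 19

    def test_matches_mu_times_chord(self, small_geometry):
        """Simulated noiseless pair: Delta p equals mu * chord per column."""
        mu = np.array([0.02, 0.015, 0.012, 0.01])
        flux = np.full(4, 1e4)
        empty, filled = simulate_projection_pair(small_geometry, mu, flux)
        chords = chord_lengths(small_geometry)
        dp = profile_difference(LineProfile.from_frame(filled[0], 0),
                                LineProfile.from_frame(empty[0], 0))
        np.testing.assert_allclose(dp.values, mu[0] * chords,
                                   rtol=1e-3, atol=1e-10)


def reference_two_stage_filter(values):
    """Independent loop implementation: truncated centred mean(5) then
    median(7)."""
    n = len(values)
    stage1 = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        stage1[i] = np.mean(values[lo:hi])
    stage2 = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 3), min(n, i + 4)
        stage2[i] = np.median(stage1[lo:hi])
    return stage2


class TestDenoiseProfile:
    def test_constant_preserved(self):
        p = denoise_profile(profile(np.full(40, 3.0)))
        np.testing.assert_allclose(p.values, 3.0)

    def test_single_spike_removed(self):
        vals = np.full(60, 1.0)
        vals[30] = 50.0
        p = denoise_profile(profile(vals))
        assert p.values[30] < 12.0  # mean stage spreads, median removes

    def test_matches_reference_filter(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5.0, 1.0, size=501)
        p = denoise_profile(profile(vals))
        np.testing.assert_allclose(p.values, reference_two_stage_filter(vals),
                                   rtol=1e-12)

    def test_filters_skip_masked_columns(self):
        vals = np.ones(30)
        vals[10] = 1e9  # masked, must not leak into neighbours
        mask = np.ones(30, dtype=bool)
        mask[10] = False
        p = denoise_profile(profile(vals, mask))
        np.testing.assert_allclose(p.values[p.valid_mask], 1.0)


class TestIntegrateLac:
    def test_zero_profile(self, geometry):
        assert integrate_lac(profile(np.zeros(1280)), geometry) == 0.0

    def test_parallel_beam_identity(self, geometry):
        """Parallel rays, magnification 1: integral of chord over the
        shadow is exactly L^2, so the input mu comes back."""
        mu0 = 0.02
        chords = chord_lengths(geometry, parallel=True)
        xs_pix = geometry.pixel_pitch_mm
        dp = profile(mu0 * chords)
        rec = integrate_lac(dp, geometry, force_magnification=1.0)
        assert rec == pytest.approx(mu0, rel=1e-3)

    def test_diverging_beam_weak_perspective_bound(self, geometry):
        """Exact fan-beam chords, demagnified: within 3% of truth."""
        mu0 = 0.025
        dp = profile(mu0 * chord_lengths(geometry))
        rec = integrate_lac(dp, geometry)
        assert abs(rec - mu0) / mu0 <= 0.03

    def test_masked_columns_interpolated(self, geometry):
        mu0 = 0.02
        vals = mu0 * chord_lengths(geometry, parallel=True)
        mask = np.ones_like(vals, dtype=bool)
        mask[500:510] = False
        vals2 = vals.copy()
        vals2[500:510] = 123.0  # garbage in masked region must be ignored
        rec = integrate_lac(profile(vals2, mask), geometry,
                            force_magnification=1.0)
        assert rec == pytest.approx(mu0, rel=2e-3)

    def test_incomplete_shadow_warns(self, geometry):
        vals = np.full(1280, 1.0)  # profile never returns to baseline
        with pytest.warns(UserWarning, match="shadow"):
            integrate_lac(profile(vals), geometry)


class TestFullChain:
    MU = np.array([0.02, 0.015, 0.012, 0.01])
    FLUX = np.full(4, 1e4)

    def test_parallel_extraction_exact(self, small_geometry):
        empty, filled = simulate_projection_pair(
            small_geometry, self.MU, self.FLUX, parallel=True)
        for b in range(4):
            rec = extract_lac_profile(
                LineProfile.from_frame(filled[b], 0),
                LineProfile.from_frame(empty[b], 0),
                small_geometry, force_magnification=1.0)
            assert rec == pytest.approx(self.MU[b], rel=1e-3)

    def test_diverging_extraction_within_3_percent(self, small_geometry):
        empty, filled = simulate_projection_pair(
            small_geometry, self.MU, self.FLUX)
        for b in range(4):
            rec = extract_lac_profile(
                LineProfile.from_frame(filled[b], 0),
                LineProfile.from_frame(empty[b], 0), small_geometry)
            assert abs(rec - self.MU[b]) / self.MU[b] <= 0.03

    def test_enclosure_attenuation_cancels(self, small_geometry):
        """Multiplying empty and filled by the same enclosure transmission
        leaves the extracted LAC unchanged."""
        kw = dict(mu_per_bin=self.MU, flux_per_bin=self.FLUX)
        plain = simulate_projection_pair(small_geometry, **kw)
        rng = np.random.default_rng(0)
        trans = rng.uniform(0.5, 0.9, size=small_geometry.detector_shape[1])
        walled = simulate_projection_pair(
            small_geometry, enclosure_transmission=trans, **kw)
        for variant_b, plain_b in zip(zip(*walled), zip(*plain)):
            rec_w = extract_lac_profile(
                LineProfile.from_frame(variant_b[1], 0),
                LineProfile.from_frame(variant_b[0], 0), small_geometry)
            rec_p = extract_lac_profile(
                LineProfile.from_frame(plain_b[1], 0),
                LineProfile.from_frame(plain_b[0], 0), small_geometry)
            assert rec_w == pytest.approx(rec_p, rel=1e-6)


class TestLacWithVariance:
    MU = np.array([0.02, 0.015, 0.012, 0.01])
    FLUX = np.full(4, 2e4)

    def test_noiseless_variance_zero(self, small_geometry):
        empty, filled = simulate_projection_pair(small_geometry, self.MU, self.FLUX)
        m = lac_with_variance(filled, empty, small_geometry, center_row=0,
                              n_loi=10)
        np.testing.assert_allclose(m.variance, 0.0, atol=1e-30)
        np.testing.assert_allclose(m.mu_per_bin, self.MU, rtol=0.03)

    def test_variance_scales_inversely_with_flux(self, small_geometry):
        """Quadrupling the flux should reduce the LOI variance roughly
        fourfold (averaged over seeds)."""
        ratios = []
        for seed in range(20):
            vs = []
            for flux_scale in (1.0, 4.0):
                empty, filled = simulate_projection_pair(
                    small_geometry, self.MU, self.FLUX * flux_scale,
                    noise=True, seed=seed)
                m = lac_with_variance(filled, empty, small_geometry,
                                      center_row=0, n_loi=10)
                vs.append(m.variance.mean())
            ratios.append(vs[0] / vs[1])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.5)

    def test_single_loi_mean_defined_variance_errors(self, small_geometry):
        empty, filled = simulate_projection_pair(small_geometry, self.MU, self.FLUX)
        m = lac_with_variance(filled, empty, small_geometry, center_row=0,
                              n_loi=1)
        np.testing.assert_allclose(m.mu_per_bin, self.MU, rtol=0.03)
        with pytest.raises(VarianceUnavailableError):
            m.variance

    def test_rows_outside_frame_rejected(self, small_geometry):
        empty, filled = simulate_projection_pair(small_geometry, self.MU, self.FLUX)
        with pytest.raises(ValueError):
            lac_with_variance(filled, empty, small_geometry, center_row=8,
                              n_loi=10)


def test_measure_scene_roundtrip(small_geometry, bases):
    """Threshold acquisition -> bins -> LOI chain recovers the series LAC."""
    from pcctherm import make_phantom_scene
    series = bases.bases[2]
    scene = make_phantom_scene(small_geometry, series, 43.0, noise=False)
    m = measure_scene(scene, small_geometry, center_row=0)
    true = series.lac_at(43.0).mu_per_bin
    np.testing.assert_allclose(m.mu_per_bin, true, rtol=0.03)
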