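import numpy as np
import pytest

from wfmap import (candidate_filter, diffuse_map, fit_amplitude_model,
                   fit_tuning_model, scan_diffusion_scales, to_octaves)
from wfmap.montecarlo import SensitivityProfile


@pytest.fixture
def gaussian_profile():
    """A synthetic sensitivity profile (Gaussian, FWHM 0.63 mm) standing in
    for a simulated one; used purely as a diffusion kernel shape."""
    offsets = np.arange(-60, 61) * 0.033
    sigma = 0.63 / (2 * np.sqrt(2 * np.log(2)))
    vals = np.exp(-offsets**2 / (2 * sigma**2))
    return SensitivityProfile(offsets, vals, 0.63, sigma, 0, 0)


class TestCandidateFilter:
    def test_both_thresholds_pass(self):
        keep = candidate_filter(np.array([[0.3e-3]]), np.array([[2.0e-3]]),
                                np.array([[True]]), np.array([[True]]))
        assert keep[0, 0]

    def test_weak_skull_amplitude_dropped(self):
        keep = candidate_filter(np.array([[0.1e-3]]), np.array([[2.0e-3]]),
                                np.array([[True]]), np.array([[True]]))
        assert not keep[0, 0]

    def test_empty_region_mask_empty_selection(self):
        keep = candidate_filter(np.full((3, 3), 1e-3), np.full((3, 3), 2e-3),
                                np.ones((3, 3), bool), np.ones((3, 3), bool),
                                region_mask=np.zeros((3, 3), bool))
        assert not keep.any()

    def test_invalid_tuning_dropped(self):
        keep = candidate_filter(np.array([[0.3e-3]]), np.array([[2.0e-3]]),
                                np.array([[False]]), np.array([[True]]))
        assert not keep[0, 0]


class TestDiffuseMap:
    def test_pitch_scale_is_identity(self, gaussian_profile):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(20, 20)) + 1j * rng.normal(size=(20, 20))
        out = diffuse_map(z, gaussian_profile, 0.05, 0.05)
        assert np.allclose(out, z, atol=1e-6)

    def test_uniform_phase_is_preserved(self, gaussian_profile):
        rng = np.random.default_rng(1)
        amp = rng.uniform(0.5, 1.5, (30, 30))
        z = amp * np.exp(1j * 0.7)
        out = diffuse_map(z, gaussian_profile, 0.4, 0.05)
        inner = out[5:-5, 5:-5]
        assert np.allclose(np.angle(inner), 0.7, atol=1e-9)

    def test_opposite_phases_cancel(self, gaussian_profile):
        z = np.zeros((21, 21), dtype=complex)
        z[10, 10] = 1.0
        z[10, 11] = -1.0
        out = diffuse_map(z, gaussian_profile, 0.4, 0.05)
        coherent = np.abs(out).sum()
        incoherent = (np.abs(diffuse_map(np.abs(z).astype(complex),
                                         gaussian_profile, 0.4, 0.05))).sum()
        assert coherent < 0.5 * incoherent

    def test_constant_field_is_fixed_point(self, gaussian_profile):
        z = np.full((100, 100), 2.0 + 1.0j)
        out = diffuse_map(z, gaussian_profile, 0.4, 0.05)
        inner = out[30:-30, 30:-30]  # beyond the kernel's reach of the edges
        assert np.allclose(inner, 2.0 + 1.0j, atol=1e-9)

    def test_nonpositive_target_rejected(self, gaussian_profile):
        with pytest.raises(ValueError):
            diffuse_map(np.ones((4, 4), complex), gaussian_profile, 0.0, 0.05)


class TestLinearFits:
    def test_exact_proportionality_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.5, 3.0, 300)
        fit = fit_amplitude_model(x, 0.125 * x)
        assert np.isclose(fit.slope, 0.125, atol=1e-9)
        assert np.isclose(fit.r2, 1.0, atol=1e-12)

    def test_unit_slope(self):
        x = np.linspace(1, 5, 50)
        assert np.isclose(fit_amplitude_model(x, x).slope, 1.0)

    def test_ols_slope_matches_normal_equation(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 200)
        y = 0.4 * x + rng.normal(0, 0.05, 200)
        fit = fit_amplitude_model(x, y, robust=False)
        assert np.isclose(fit.slope, (x @ y) / (x @ x), atol=1e-10)

    def test_robust_matches_ols_on_clean_data(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.5, 2.0, 400)
        y = 0.7 * x
        a = fit_amplitude_model(x, y, robust=True)
        b = fit_amplitude_model(x, y, robust=False)
        assert np.isclose(a.slope, b.slope, atol=1e-6)

    def test_tuning_model_coefficients_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 6, 500)
        y = 0.675 * x + 0.502 + rng.normal(0, 0.01, 500)
        fit = fit_tuning_model(x, y, robust=False)
        assert np.isclose(fit.slope, 0.675, atol=0.01)
        assert np.isclose(fit.intercept, 0.502, atol=0.01)

    def test_identity_tuning(self):
        x = np.linspace(0, 6, 100)
        fit = fit_tuning_model(x, x, robust=False)
        assert np.isclose(fit.slope, 1.0) and np.isclose(fit.intercept, 0.0,
                                                         atol=1e-12)

    def test_octave_conversion(self):
        assert to_octaves(440.0) == 0.0
        assert np.isclose(to_octaves(28160.0), 6.0)


def _smooth_complex_field(shape, rng, corr_px=6):
    from scipy.ndimage import gaussian_filter
    re = gaussian_filter(rng.normal(size=shape), corr_px)
    im = gaussian_filter(rng.normal(size=shape), corr_px)
    z = re + 1j * im
    return z / np.abs(z).mean()


class TestScanDiffusionScales:
    def test_planted_scale_recovered(self, gaussian_profile):
        rng = np.random.default_rng(6)
        window = _smooth_complex_field((90, 90), rng)
        pitch = 0.05
        skull = diffuse_map(window, gaussian_profile, 0.6, pitch)
        skull += 0.01 * (rng.normal(size=skull.shape)
                         + 1j * rng.normal(size=skull.shape))
        scales = np.arange(0.2, 1.21, 0.1)
        scan = scan_diffusion_scales(window, skull, gaussian_profile, scales,
                                     pitch)
        assert abs(scan.best_scale_amplitude_mm - 0.6) <= 0.1 + 1e-9
        assert abs(scan.best_scale_tuning_mm - 0.6) <= 0.1 + 1e-9

    def test_identical_maps_prefer_smallest_scale(self, gaussian_profile):
        rng = np.random.default_rng(7)
        window = _smooth_complex_field((60, 60), rng)
        scales = np.array([0.05, 0.3, 0.6])
        scan = scan_diffusion_scales(window, window, gaussian_profile, scales,
                                     0.05)
        assert scan.best_scale_amplitude_mm == 0.05
        assert np.isclose(scan.r2_amplitude[0], 1.0, atol=1e-9)

    def test_r2_bounded(self, gaussian_profile):
        rng = np.random.default_rng(8)
        window = _smooth_complex_field((50, 50), rng)
        skull = _smooth_complex_field((50, 50), rng)
        scan = scan_diffusion_scales(window, skull, gaussian_profile,
                                     np.array([0.1, 0.4, 0.8]), 0.05)
        assert np.all(scan.r2_amplitude <= 1.0)
        assert np.all(scan.r2_tuning <= 1.0)

    def test_geometry_mismatch_rejected(self, gaussian_profile):
        with pytest.raises(ValueError):
            scan_diffusion_scales(np.ones((4, 4), complex),
                                  np.ones((5, 5), complex),
                                  gaussian_profile, np.array([0.3]), 0.05)
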