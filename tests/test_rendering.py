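import numpy as np
import pytest

from wfmap import (RenderSpec, apply_affine, estimate_affine, iso_t_contours,
                   render_hsv, render_retinotopy_composite, render_rgb_summary,
                   tonotopy_validity)
from wfmap.maps import ResponseMap, TuningMap
from wfmap.schedules import StimulusChannel, StimulusEvent


def _tmap(amp, phase=None, T=20.0, delay=None, valid=None):
    amp = np.asarray(amp, dtype=float)
    phase = np.zeros_like(amp) if phase is None else np.asarray(phase, float)
    return TuningMap(phase, amp, T, delay_s=delay, valid=valid)


class TestRenderHsv:
    def test_99th_percentile_pixel_saturates(self):
        rng = np.random.default_rng(0)
        amp = rng.uniform(0.1, 1.0, (40, 40))
        tmap = _tmap(amp)
        upper = RenderSpec().upper(tmap.amplitude, tmap.valid)
        assert np.isclose(upper, np.percentile(amp, 99))
        rgb = render_hsv(tmap)
        i, j = np.unravel_index(np.argmin(np.abs(amp - upper)), amp.shape)
        assert rgb[i, j].max() >= 0.999  # value channel = 1 at the upper limit

    def test_about_one_percent_clipped_at_default(self):
        rng = np.random.default_rng(1)
        amp = rng.uniform(0.0, 1.0, (100, 100))
        tmap = _tmap(amp)
        upper = RenderSpec().upper(tmap.amplitude, tmap.valid)
        assert abs((amp > upper).sum() - 100) <= 1

    def test_zero_amplitude_renders_black(self):
        amp = np.array([[0.0, 1.0]])
        rgb = render_hsv(_tmap(amp, valid=np.array([[True, True]])))
        assert np.allclose(rgb[0, 0], 0.0)

    def test_phases_a_cycle_apart_share_hue(self):
        tmap = _tmap([[1.0, 1.0]], phase=[[0.25, 0.25]])
        tmap2 = _tmap([[1.0, 1.0]], phase=[[0.25, 20.25 % 20.0]])
        assert np.allclose(render_hsv(tmap), render_hsv(tmap2))

    def test_all_invalid_renders_gray_with_warning(self, caplog):
        tmap = _tmap([[1.0]], valid=np.array([[False]]))
        with caplog.at_level("WARNING", logger="wfmap"):
            rgb = render_hsv(tmap)
        assert np.allclose(rgb, 0.5)
        assert "no valid pixels" in caplog.text

    def test_monotone_in_amplitude(self):
        amp = np.array([[0.2, 0.4, 0.9]])
        spec = RenderSpec(amplitude_upper=1.0)
        rgb = render_hsv(_tmap(amp), spec)
        intensity = rgb.max(axis=-1)[0]
        assert intensity[0] < intensity[1] < intensity[2]


class TestTonotopyValidity:
    def test_phase_in_silence_invalid(self):
        tmap = _tmap([[1.0]], phase=[[1.0]])
        assert not tonotopy_validity(tmap, (2.7, 17.3))[0, 0]

    def test_phase_and_delay_in_range_valid(self):
        tmap = _tmap([[1.0]], phase=[[5.0]], delay=np.array([[3.9]]))
        assert tonotopy_validity(tmap, (2.7, 17.3))[0, 0]

    def test_delay_out_of_acceptance_invalid(self):
        tmap = _tmap([[1.0]], phase=[[5.0]], delay=np.array([[6.5]]))
        assert not tonotopy_validity(tmap, (2.7, 17.3))[0, 0]


class TestRetinotopyComposite:
    def _maps(self, ecc_phase, motion_amp):
        polar = _tmap([[1.0]], phase=[[0.0]])
        ecc = _tmap([[1.0]], phase=[[ecc_phase]])
        motion = ResponseMap(np.array([[motion_amp]]), np.array([[0.0]]), 20.0)
        return polar, ecc, motion

    def test_center_preferring_motion_pixel_is_white(self):
        # eccentricity phase at mid-cycle = center zone -> saturation 0
        rgb = render_retinotopy_composite(*self._maps(10.0, 1.0),
                                          RenderSpec(amplitude_upper=1.0))
        assert np.allclose(rgb[0, 0], 1.0)

    def test_zero_motion_is_black(self):
        rgb = render_retinotopy_composite(*self._maps(10.0, 0.0),
                                          RenderSpec(amplitude_upper=1.0))
        assert np.allclose(rgb[0, 0], 0.0)

    def test_periphery_pixel_fully_saturated(self):
        rgb = render_retinotopy_composite(*self._maps(0.0, 1.0),
                                          RenderSpec(amplitude_upper=1.0))
        # saturation 1 at hue 0 (red by default): pure spectral color
        assert np.allclose(rgb[0, 0], [1.0, 0.0, 0.0])

    def test_geometry_mismatch_rejected(self):
        polar, ecc, _ = self._maps(0.0, 1.0)
        motion = ResponseMap(np.ones((2, 2)), np.zeros((2, 2)), 20.0)
        with pytest.raises(ValueError):
            render_retinotopy_composite(polar, ecc, motion)


class TestRgbSummary:
    def _channel(self, T=20.0):
        return StimulusChannel("c", T, 20, events=[StimulusEvent(8.0, 4.0, 1.0)])

    def test_pixel_at_stimulus_center_included(self):
        tmap = _tmap([[1.0]], phase=[[10.0]])
        out = render_rgb_summary([tmap], [self._channel()],
                                 spec=RenderSpec(amplitude_upper=1.0))
        assert out[0, 0, 0] == 1.0

    def test_pixel_past_tolerance_excluded(self):
        # window 8-12 s +- 1 s; phase 13.5 s = 1.5 s after offset
        tmap = _tmap([[1.0]], phase=[[13.5]])
        out = render_rgb_summary([tmap], [self._channel()],
                                 spec=RenderSpec(amplitude_upper=1.0))
        assert out[0, 0, 0] == 0.0

    def test_disjoint_regions_have_no_mixed_colors(self):
        a = _tmap([[1.0, 0.0]], phase=[[10.0, 0.0]],
                  valid=np.array([[True, False]]))
        b = _tmap([[0.0, 1.0]], phase=[[0.0, 10.0]],
                  valid=np.array([[False, True]]))
        out = render_rgb_summary([a, b], [self._channel(), self._channel()],
                                 spec=RenderSpec(amplitude_upper=1.0))
        assert (np.count_nonzero(out, axis=-1) <= 1).all()

    def test_more_than_three_channels_rejected(self):
        maps = [_tmap([[1.0]])] * 4
        with pytest.raises(ValueError, match="3"):
            render_rgb_summary(maps, [self._channel()] * 4)


class TestAffine:
    def test_identity_landmarks(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [7.0, 3.0]])
        tr = estimate_affine(pts, pts)
        assert np.allclose(tr.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)

    def test_pure_translation_recovered(self):
        pts = np.array([[0.0, 0.0], [5.0, 1.0], [2.0, 8.0]])
        tr = estimate_affine(pts, pts + [2.0, -3.0])
        assert np.allclose(tr.matrix[:, 2], [2.0, -3.0])
        assert np.allclose(tr.matrix[:, :2], np.eye(2))

    def test_random_affine_round_trip(self):
        rng = np.random.default_rng(2)
        M = np.array([[1.1, 0.2, 3.0], [-0.1, 0.9, -2.0]])
        src = rng.uniform(0, 50, (8, 2))
        dst = src @ M[:, :2].T + M[:, 2]
        tr = estimate_affine(src, dst)
        assert np.allclose(tr.matrix, M, atol=1e-9)
        back = tr.inverse()(tr(src))
        assert np.allclose(back, src, atol=1e-9)

    def test_collinear_landmarks_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_affine(pts, pts)

    def test_apply_affine_preserves_interior_valid_count(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[20:40, 20:40] = True
        tr = estimate_affine(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                             np.array([[3.0, 2.0], [4.0, 2.0], [3.0, 3.0]]))
        moved = apply_affine(mask, tr, (60, 60), is_mask=True)
        assert abs(moved.sum() - mask.sum()) / mask.sum() < 0.02


class TestIsoTContours:
    def test_constant_field_no_contours(self):
        out = iso_t_contours(np.full((20, 20), 1.5), [2.0])
        assert out[2.0] == []

    def test_gaussian_peak_closed_loop(self):
        y, x = np.mgrid[-20:21, -20:21]
        t = 5.0 * np.exp(-(x**2 + y**2) / 50.0)
        (loop,) = iso_t_contours(t, [2.0])[2.0]
        assert np.allclose(loop[0], loop[-1])  # closed
        r = np.hypot(loop[:, 0] - 20, loop[:, 1] - 20)
        expected = np.sqrt(50.0 * np.log(5.0 / 2.0))
        assert np.allclose(r, expected, atol=0.5)

    def test_level_above_max_empty(self):
        y, x = np.mgrid[-5:6, -5:6]
        t = np.exp(-(x**2 + y**2) / 4.0)
        assert iso_t_contours(t, [2.0])[2.0] == []
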