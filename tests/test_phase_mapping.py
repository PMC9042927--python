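import numpy as np
import pytest

from wfmap import (DEFAULT_POLARITY, Movie, SessionConfig, StimulusChannel,
                   StimulusEvent, compensate_delay, extract_channel_response,
                   parcellate, pixel_spectrum, synthesize_movie)
from wfmap.synthetic import GroundTruth, random_truth

from conftest import make_truth


def brute_force_dft(trace):
    """Direct-summation DFT oracle."""
    n = len(trace)
    j = np.arange(n)
    return np.array([np.sum(trace * np.exp(-2j * np.pi * k * j / n))
                     for k in range(n // 2 + 1)])


class TestPixelSpectrum:
    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(size=32) * 1e-3
        movie = Movie(trace.reshape(-1, 1, 1), 1.0, kind="relative")
        coefs = pixel_spectrum(movie).coefs[:, 0, 0]
        assert np.allclose(coefs, brute_force_dft(trace), atol=1e-10)

    def test_exact_bin_concentration(self):
        # cos at 20 cycles over a 400 s session: all power in the 0.05 Hz bin
        t = (np.arange(2000) + 0.5) / 5.0
        movie = Movie((1e-3 * np.cos(2 * np.pi * t / 20)).reshape(-1, 1, 1),
                      5.0, kind="relative")
        spec = pixel_spectrum(movie)
        amps = np.abs(spec.coefs[:, 0, 0])
        k = spec.bin_of(0.05)
        others = np.delete(amps, k)
        assert amps[k] > 1e9 * others.max()

    def test_constant_trace_has_no_ac_power(self):
        movie = Movie(np.full((100, 1, 1), 1e-3), 5.0, kind="relative")
        amps = np.abs(pixel_spectrum(movie).coefs[1:, 0, 0])
        assert np.all(amps < 1e-12)

    def test_off_bin_frequency_rejected(self):
        movie = Movie(np.zeros((100, 1, 1)), 5.0, kind="relative")
        with pytest.raises(ValueError, match="exact spectral bin"):
            pixel_spectrum(movie).bin_of(0.033)


class TestExtractChannelResponse:
    def test_phase_is_peak_time_of_compensated_cosine(self, planted_movie):
        movie, truth, config = planted_movie
        rmap = extract_channel_response(pixel_spectrum(movie),
                                        config.channels[0], polarity=-1)
        assert np.allclose(rmap.phase_time_s, 9.0, atol=1e-9)
        assert np.allclose(rmap.amplitude, 1e-3, rtol=1e-9)

    def test_zero_trace_masked(self, single_channel_config):
        movie = Movie(np.zeros((2000, 1, 1)), 5.0, kind="relative")
        rmap = extract_channel_response(pixel_spectrum(movie),
                                        single_channel_config.channels[0], -1)
        assert not rmap.valid[0, 0]

    def test_uncompensated_polarity_shifts_phase_half_cycle(self, planted_movie):
        movie, _, config = planted_movie
        spec = pixel_spectrum(movie)
        ok = extract_channel_response(spec, config.channels[0], -1)
        flipped = extract_channel_response(spec, config.channels[0], +1)
        shift = (flipped.phase_time_s - ok.phase_time_s) % 20.0
        assert np.allclose(shift, 10.0, atol=1e-9)

    def test_amplitude_invariant_to_constant_offset(self, planted_movie):
        movie, _, config = planted_movie
        shifted = Movie(movie.frames + 5e-4, movie.frame_rate_hz, kind="relative")
        a = extract_channel_response(pixel_spectrum(movie), config.channels[0], -1)
        b = extract_channel_response(pixel_spectrum(shifted), config.channels[0], -1)
        assert np.allclose(a.amplitude, b.amplitude, atol=1e-15)

    def test_random_planted_phase_recovery(self, single_channel_config):
        # 1000 random (preferred time, delay) pairs recovered noise-free
        truth = random_truth((25, 40), ["tones"], [20.0], seed=3,
                             delay_range_s=(0.0, 20.0))
        movie = synthesize_movie(truth, single_channel_config, 0.0)
        rmap = extract_channel_response(pixel_spectrum(movie),
                                        single_channel_config.channels[0], -1)
        planted = (truth.preferred_time_s["tones"] + truth.delay_s) % 20.0
        err = np.abs((rmap.phase_time_s - planted + 10.0) % 20.0 - 10.0)
        assert err.max() < 0.5 / single_channel_config.frame_rate_hz

    def test_parseval_energy_bound(self, single_channel_config):
        truth = random_truth((4, 4), ["tones"], [20.0], seed=5)
        movie = synthesize_movie(truth, single_channel_config, 0.3, seed=5)
        spec = pixel_spectrum(movie)
        n = spec.n_samples
        # one-sided bin amplitudes (2|c|/N); DC and Nyquist excluded from doubling
        amp2 = (2 * np.abs(spec.coefs[1:-1]) / n) ** 2
        var = movie.frames.var(axis=0)
        assert np.all(amp2.sum(axis=0) <= 2 * var + 1e-15)


class TestCompensateDelay:
    def test_tonotopy_delay_subtraction(self, planted_movie):
        movie, _, config = planted_movie
        rmap = extract_channel_response(pixel_spectrum(movie),
                                        config.channels[0], -1)
        rmap.phase_time_s[:] = 8.9
        tmap = compensate_delay(rmap, 3.9)
        assert np.allclose(tmap.tuning_phase_s, 5.0)

    def test_wraps_below_zero(self, planted_movie):
        movie, _, config = planted_movie
        rmap = extract_channel_response(pixel_spectrum(movie),
                                        config.channels[0], -1)
        rmap.phase_time_s[:] = 1.0
        rmap.period_s = 18.0
        tmap = compensate_delay(rmap, 3.7)
        assert np.allclose(tmap.tuning_phase_s, 15.3)

    def test_zero_delay_is_identity(self, planted_movie):
        movie, _, config = planted_movie
        rmap = extract_channel_response(pixel_spectrum(movie),
                                        config.channels[0], -1)
        tmap = compensate_delay(rmap, 0.0)
        assert np.allclose(tmap.tuning_phase_s, rmap.phase_time_s)


def _three_modality_setup(noise=0.0, seed=0):
    channels = [
        StimulusChannel("som", 22.0, 18, events=[StimulusEvent(8.0, 6.0, 1.0)]),
        StimulusChannel("aud", 19.8, 20, events=[StimulusEvent(5.0, 9.8, 1.0)]),
        StimulusChannel("vis", 18.0, 22, events=[StimulusEvent(7.0, 4.0, 1.0)]),
    ]
    config = SessionConfig(530.0, 5.0, 396.0, channels)
    shape = (6, 9)
    regions = {"som": (slice(None), slice(0, 3)),
               "aud": (slice(None), slice(3, 6)),
               "vis": (slice(None), slice(6, 9))}
    preferred, amplitude = {}, {}
    for ch in channels:
        amp = np.zeros(shape)
        amp[regions[ch.label]] = 1e-3
        amplitude[ch.label] = amp
        preferred[ch.label] = np.full(shape, ch.cycle_period_s / 2 - 4.0)
    truth = GroundTruth(preferred, amplitude, np.full(shape, 4.0))
    movie = synthesize_movie(truth, config, noise, seed=seed)
    return movie, config, regions


class TestParcellate:
    def test_disjoint_regions_separate_cleanly(self):
        movie, config, regions = _three_modality_setup()
        maps = parcellate(movie, config)
        for label, rmap in maps.items():
            inside = rmap.amplitude[regions[label]]
            outside_mask = np.ones(rmap.shape, dtype=bool)
            outside_mask[regions[label]] = False
            outside = rmap.amplitude[outside_mask]
            assert inside.min() >= 100 * max(outside.max(), 1e-30)

    def test_channel_orthogonality_noise_free(self):
        movie, config, regions = _three_modality_setup()
        maps = parcellate(movie, config)
        # off-channel amplitude < 1e-9 of on-channel amplitude
        for label, rmap in maps.items():
            on = rmap.amplitude[regions[label]].min()
            outside_mask = np.ones(rmap.shape, dtype=bool)
            outside_mask[regions[label]] = False
            assert rmap.amplitude[outside_mask].max() < 1e-9 * on

    def test_shared_bin_rejected(self):
        ch1 = StimulusChannel("a", 20.0, 20)
        ch2 = StimulusChannel("b", 20.0, 20)
        config = SessionConfig(530.0, 5.0, 400.0, [ch1, ch2])
        movie = Movie(np.zeros((2000, 1, 1)), 5.0, kind="relative")
        with pytest.raises(ValueError, match="share"):
            parcellate(movie, config)

    def test_polarity_comes_from_wavelength(self):
        movie, config, regions = _three_modality_setup()
        maps_green = parcellate(movie, config)
        config_red = SessionConfig(625.0, 5.0, 396.0, config.channels)
        maps_red = parcellate(movie, config_red)
        shift = (maps_red["som"].phase_time_s - maps_green["som"].phase_time_s) % 22.0
        assert np.allclose(shift[maps_green["som"].valid], 11.0, atol=1e-6)


def test_polarity_table_defaults():
    assert DEFAULT_POLARITY.sign(530) == -1
    assert DEFAULT_POLARITY.sign(850) == -1
    assert DEFAULT_POLARITY.sign(625) == +1
    assert DEFAULT_POLARITY.is_ambiguous(590)
    with pytest.raises(KeyError):
        DEFAULT_POLARITY.sign(600)
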