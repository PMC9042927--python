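"""Per-pixel spectral analysis of phase-encoded sessions.

Each pixel's dR/R trace over a whole session is Fourier transformed; the
complex coefficient at a stimulus channel's cycle frequency carries the
response amplitude (2|c|/N, so a unit cosine reads out as 1) and the
response phase, expressed as the peak time of the polarity-compensated
cosine fit within the cycle.  Because every channel period divides the
session duration exactly, channels occupy orthogonal spectral bins and a
single session can be parcellated into simultaneous modality maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import Movie, SessionConfig
from .maps import DEFAULT_POLARITY, PolarityTable, ResponseMap, TuningMap
from .schedules import StimulusChannel

#: fixed hemodynamic-delay compensations (s) for single-session analyses,
#: the group averages over candidate pixels of the reversed-session pairs
DELAY_TONOTOPY_S = 3.9
DELAY_RETINOTOPY_POLAR_S = 3.5
DELAY_DEFAULT_S = 3.7


@dataclass
class PixelSpectrum:
    """One-sided DFT of every pixel trace.

    ``coefs[k]`` is the raw (unnormalized) DFT coefficient at frequency
    ``freqs_hz[k] = k / duration``; ``n_samples`` and ``frame_rate_hz`` are
    kept for amplitude normalization and the frame-center phase reference.
    """

    coefs: np.ndarray  # (n_bins, rows, cols), complex
    freqs_hz: np.ndarray
    n_samples: int
    frame_rate_hz: float

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.frame_rate_hz

    def bin_of(self, frequency_hz: float) -> int:
        """Exact bin index of a frequency; raises off-bin (spectral leakage
        would silently corrupt phases)."""
        k = frequency_hz * self.duration_s
        if abs(k - round(k)) > 1e-6:
            raise ValueError(
                f"{frequency_hz} Hz is not an exact spectral bin "
                f"(bin spacing {1 / self.duration_s} Hz)"
            )
        k = int(round(k))
        if not 0 <= k < self.coefs.shape[0]:
            raise ValueError(f"frequency {frequency_hz} Hz outside spectrum")
        return k


def pixel_spectrum(movie: Movie) -> PixelSpectrum:
    """DFT along time per pixel (one-sided; bin spacing 1/duration).

    No windowing or detrending is applied: the constant offset lands in the
    DC bin and the stimulus frequencies are exact bins by construction.
    """
    if movie.kind != "relative":
        raise ValueError("pixel_spectrum expects a relative (dR/R) movie")
    coefs = np.fft.rfft(movie.frames, axis=0)
    freqs = np.fft.rfftfreq(movie.n_frames, d=1.0 / movie.frame_rate_hz)
    return PixelSpectrum(coefs, freqs, movie.n_frames, movie.frame_rate_hz)


def extract_channel_response(spectrum: PixelSpectrum, channel: StimulusChannel,
                             polarity: int = -1) -> ResponseMap:
    """Amplitude and phase-time map at one channel's stimulus frequency.

    The trace is polarity-multiplied (equivalently, the bin coefficient is),
    so that a response *to* the stimulus is a positive-going cosine; the
    phase is then referenced to the frame-center timestamps so that a cosine
    peaking at cycle time ``t0`` yields ``phase_time_s = t0`` exactly.
    Pixels with zero or non-finite amplitude are masked invalid.
    """
    if polarity not in (-1, +1):
        raise ValueError("polarity must be +1 or -1")
    k = spectrum.bin_of(channel.frequency_hz)
    c = polarity * spectrum.coefs[k]
    n = spectrum.n_samples
    amplitude = 2.0 * np.abs(c) / n
    # frame j sits at t_j=(j+0.5)/fs: the DFT implicitly references t=0 at
    # sample 0, so the half-sample offset contributes a phase pi*k/n
    T = 1.0 / channel.frequency_hz
    phase = (np.pi * k / n - np.angle(c)) * T / (2 * np.pi)
    phase = np.mod(phase, T)
    valid = np.isfinite(amplitude) & (amplitude > 0)
    phase = np.where(valid, phase, 0.0)
    return ResponseMap(amplitude, phase, T, label=channel.label,
                       polarity_compensated=True, valid=valid)


def compensate_delay(rmap: ResponseMap, delay_s: float = DELAY_DEFAULT_S) -> TuningMap:
    """Subtract a fixed hemodynamic delay from the raw phase time (mod T).

    Use :data:`DELAY_TONOTOPY_S` (3.9 s), :data:`DELAY_RETINOTOPY_POLAR_S`
    (3.5 s) or the 3.7 s default depending on the experiment; reversed
    session pairs instead derive the delay per pixel
    (:func:`wfmap.delay_mapping.combine_reversed_sessions`).
    """
    if not rmap.polarity_compensated:
        raise ValueError("compensate polarity before delay")
    tuning = np.mod(rmap.phase_time_s - delay_s, rmap.period_s)
    return TuningMap(tuning, rmap.amplitude.copy(), rmap.period_s,
                     valid=rmap.valid.copy(), label=rmap.label)


def parcellate(movie: Movie, config: SessionConfig,
               polarity_table: PolarityTable = DEFAULT_POLARITY) -> dict[str, ResponseMap]:
    """One ResponseMap per stimulus channel from a single session.

    All channel frequencies must be distinct exact bins; on noise-free data
    the channels then do not interfere (orthogonal bins).
    """
    spectrum = pixel_spectrum(movie)
    bins = [spectrum.bin_of(ch.frequency_hz) for ch in config.channels]
    if len(set(bins)) != len(bins):
        raise ValueError("two channels share a spectral bin; periods must differ")
    pol = polarity_table.sign(config.wavelength_nm)
    return {ch.label: extract_channel_response(spectrum, ch, pol)
            for ch in config.channels}
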