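"""Synthetic wide-field movies with planted per-pixel ground truth.

The signal model mirrors the analysis model: each responsive pixel follows
its stimulus channel with a periodic response peaking at the preferred
stimulus time ``s`` plus the hemodynamic delay ``delta``, scaled by a
response amplitude ``A`` (dR/R) and flipped by the wavelength-dependent
polarity.  The default kernel is a pure cosine at the channel frequency,

    trace(t) = polarity * A * cos(2*pi*(t - s - delta)/T) + noise,

which makes spectral recovery exact on the channel's frequency bin; a
raised-cosine bump kernel is available for more transient, realistic
responses (its fundamental-frequency amplitude is attenuated relative to
the planted A; see docs/methods.md).  Noise is i.i.d. Gaussian per frame at
a stated permille scale, the regime of binned in-vivo recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .imaging_io import Movie, SessionConfig
from .maps import DEFAULT_POLARITY, PolarityTable


@dataclass
class GroundTruth:
    """Planted per-pixel maps, one entry per stimulus channel label.

    ``preferred_time_s[label]`` is the preferred stimulus time within that
    channel's cycle; ``amplitude[label]`` the response amplitude in dR/R
    (0 where the pixel does not follow the channel); ``delay_s`` the shared
    hemodynamic delay map in seconds.
    """

    preferred_time_s: dict[str, np.ndarray]
    amplitude: dict[str, np.ndarray]
    delay_s: np.ndarray
    kernel: Literal["cosine", "raised_cosine"] = "cosine"
    kernel_width_s: float = 4.0

    def __post_init__(self) -> None:
        self.delay_s = np.asarray(self.delay_s, dtype=float)
        for label, amp in self.amplitude.items():
            if (np.asarray(amp) < 0).any():
                raise ValueError(f"negative amplitude in channel {label!r}")
            if np.asarray(amp).shape != self.delay_s.shape:
                raise ValueError(f"shape mismatch in channel {label!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.delay_s.shape

    def modality_mask(self) -> np.ndarray:
        """Index of the strongest channel per pixel (-1 where silent)."""
        labels = list(self.amplitude)
        stack = np.stack([self.amplitude[l] for l in labels])
        out = np.argmax(stack, axis=0)
        out[stack.max(axis=0) <= 0] = -1
        return out


def synthesize_movie(truth: GroundTruth, config: SessionConfig,
                     noise_sd_permille: float = 0.0, seed: int = 0,
                     polarity_table: PolarityTable = DEFAULT_POLARITY) -> Movie:
    """Render a relative-change movie from planted ground truth.

    Channel signals add linearly (the simultaneous multi-frequency
    parcellation design relies on frequency-domain separability), noise is
    Gaussian with per-frame sd ``noise_sd_permille * 1e-3``, and the result
    is bit-reproducible for a given seed.
    """
    if noise_sd_permille < 0:
        raise ValueError("noise sd must be non-negative")
    pol = polarity_table.sign(config.wavelength_nm)
    t = (np.arange(config.n_frames) + 0.5) / config.frame_rate_hz
    frames = np.zeros((t.size, *truth.shape))
    for ch in config.channels:
        if ch.label not in truth.amplitude:
            continue
        amp = np.asarray(truth.amplitude[ch.label], dtype=float)
        peak = (np.asarray(truth.preferred_time_s[ch.label], dtype=float)
                + truth.delay_s)
        T = ch.cycle_period_s
        if truth.kernel == "cosine":
            # cos(2pi (t - peak)/T) expanded to avoid a (t, H, W) broadcast per frame
            wt = 2 * np.pi * t / T
            wp = 2 * np.pi * peak / T
            frames += pol * amp * (
                np.cos(wt)[:, None, None] * np.cos(wp)
                + np.sin(wt)[:, None, None] * np.sin(wp)
            )
        elif truth.kernel == "raised_cosine":
            w = truth.kernel_width_s
            u = (t[:, None, None] - peak) % T
            u = np.where(u > T / 2, u - T, u)  # centered distance in [-T/2, T/2)
            bump = np.where(np.abs(u) < w / 2,
                            0.5 * (1 + np.cos(2 * np.pi * u / w)), 0.0)
            frames += pol * amp * bump
        else:
            raise ValueError(f"unknown kernel {truth.kernel!r}")
    if noise_sd_permille > 0:
        rng = np.random.default_rng(seed)
        frames += rng.normal(0.0, noise_sd_permille * 1e-3, frames.shape)
    return Movie(frames, config.frame_rate_hz, kind="relative",
                 wavelength_nm=config.wavelength_nm)


def random_truth(shape: tuple[int, int], channel_labels: list[str],
                 periods_s: list[float], seed: int = 0,
                 amplitude_permille: float = 1.0,
                 delay_range_s: tuple[float, float] = (2.0, 5.7)) -> GroundTruth:
    """Uniform random preferred times and delays, constant amplitude —
    the workhorse for round-trip recovery tests."""
    rng = np.random.default_rng(seed)
    preferred = {}
    amplitude = {}
    for label, T in zip(channel_labels, periods_s):
        preferred[label] = rng.uniform(0.0, T, shape)
        amplitude[label] = np.full(shape, amplitude_permille * 1e-3)
    delay = rng.uniform(*delay_range_s, shape)
    return GroundTruth(preferred, amplitude, delay)


def time_reversed_truth(truth: GroundTruth, periods_s: dict[str, float]) -> GroundTruth:
    """Ground truth for the time-reversed session of each channel.

    A pixel preferring the stimulus presented at forward cycle time ``s``
    meets that same stimulus at ``(T - s) mod T`` when the sequence is
    reversed; amplitudes and hemodynamic delays are unchanged.
    """
    preferred = {
        label: (periods_s[label] - s) % periods_s[label]
        for label, s in truth.preferred_time_s.items()
    }
    return GroundTruth(preferred, dict(truth.amplitude), truth.delay_s.copy(),
                       kernel=truth.kernel, kernel_width_s=truth.kernel_width_s)


def shot_noise_floor(photoelectrons_per_saved_pixel_frame: float,
                     n_repetitions: int = 1) -> float:
    """Relative shot-noise sd, 1/sqrt(N_photoelectrons * n_repetitions).

    Under a Poisson model for incoherent photon arrivals the relative
    intensity fluctuation of a saved (binned) pixel-frame integrating N
    photoelectrons, averaged over ``n_repetitions`` repeats, is 1/sqrt(N*n).
    The photon budget is an explicit input because it depends on sensor
    full-well capacity and binning, which are acquisition-specific.
    """
    if photoelectrons_per_saved_pixel_frame <= 0:
        raise ValueError("photoelectron count must be positive")
    if n_repetitions <= 0:
        raise ValueError("repetition count must be positive")
    return 1.0 / np.sqrt(photoelectrons_per_saved_pixel_frame * n_repetitions)
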