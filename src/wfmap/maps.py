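"""Shared per-pixel map containers and the wavelength polarity table.

Phase is stored throughout as *time in cycle* (seconds in [0, T)), never
radians: the convention is that a noise-free, polarity-compensated cosine
response peaking at cycle time ``t0`` has phase time ``t0``.  This removes
sign-convention ambiguity and matches how published tuning maps color-code
cycle time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PolarityTable:
    """Intrinsic-signal polarity per illumination wavelength.

    Polarity is the sign of the dR/R change that indicates a *greater*
    response: at wavelengths where total hemoglobin absorption rises with
    activity (blue 470, green 530, NIR 850) the backscattered intensity
    drops, so polarity is -1; at red/far-red wavelengths the HbR decrease
    dominates and polarity is +1.  Amber (590) sits near the balance point
    and is flagged ambiguous (presumed +1).
    """

    signs: dict[float, int] = field(default_factory=lambda: {
        470.0: -1, 530.0: -1, 590.0: +1, 625.0: +1, 730.0: +1, 850.0: -1,
    })
    ambiguous: frozenset = frozenset({590.0})

    def sign(self, wavelength_nm: float) -> int:
        try:
            return self.signs[float(wavelength_nm)]
        except KeyError:
            raise KeyError(
                f"no polarity entry for {wavelength_nm} nm; known wavelengths: "
                f"{sorted(self.signs)}"
            ) from None

    def is_ambiguous(self, wavelength_nm: float) -> bool:
        return float(wavelength_nm) in self.ambiguous


DEFAULT_POLARITY = PolarityTable()


@dataclass
class ResponseMap:
    """Per-pixel complex response at one stimulus frequency.

    ``amplitude`` is in dR/R units (2|c|/N normalization: a unit cosine has
    amplitude 1); ``phase_time_s`` is the peak time of the
    polarity-compensated cosine fit, in [0, T).
    """

    amplitude: np.ndarray
    phase_time_s: np.ndarray
    period_s: float
    label: str = ""
    polarity_compensated: bool = True
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase_time_s = np.asarray(self.phase_time_s, dtype=float)
        if self.amplitude.shape != self.phase_time_s.shape:
            raise ValueError("amplitude/phase shape mismatch")
        if self.valid is None:
            self.valid = np.isfinite(self.amplitude) & (self.amplitude > 0)
        ok = self.phase_time_s[self.valid]
        if ok.size and ((ok < 0) | (ok >= self.period_s)).any():
            raise ValueError("phase times must lie in [0, period)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.amplitude.shape

    def as_complex(self) -> np.ndarray:
        """amplitude * exp(i * 2*pi * phase / T); invalid pixels are 0."""
        z = self.amplitude * np.exp(2j * np.pi * self.phase_time_s / self.period_s)
        return np.where(self.valid, z, 0.0)


@dataclass
class TuningMap:
    """A delay-compensated tuning map.

    ``tuning_phase_s`` is the preferred-stimulus time in the forward
    session's cycle timeline; ``delay_s`` (when derived from a reversed
    session pair) is the per-pixel hemodynamic delay.
    """

    tuning_phase_s: np.ndarray
    amplitude: np.ndarray
    period_s: float
    delay_s: np.ndarray | None = None
    valid: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.tuning_phase_s = np.asarray(self.tuning_phase_s, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.amplitude) & (self.amplitude > 0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.amplitude.shape

    def as_complex(self) -> np.ndarray:
        z = self.amplitude * np.exp(2j * np.pi * self.tuning_phase_s / self.period_s)
        return np.where(self.valid, z, 0.0)
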