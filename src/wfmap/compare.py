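"""Compare tuning maps of the same cortex at two resolutions.

To estimate how much a diffusing layer (the skull) blurs a cortical map,
the higher-resolution map is artificially diffused at a range of scales —
by convolving it in the complex plane, amplitude * exp(i*2*pi*phase/T), so
that phase disagreement between neighbors cancels amplitude as real
diffusion would — and each diffused map is regressed against the
lower-resolution map.  The scale maximizing r^2 is the effective blur.
Two models are used: response amplitude through the origin (no constant
term) and tuning on the octave scale with an intercept; fits are robust
(iteratively reweighted, bisquare) by default with a plain least-squares
mode for oracle checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.signal import fftconvolve

from .montecarlo import SensitivityProfile


def candidate_filter(amp_skull: np.ndarray, amp_window: np.ndarray,
                     valid_skull: np.ndarray, valid_window: np.ndarray,
                     thresholds: tuple[float, float] = (0.2e-3, 1.5e-3),
                     region_mask: np.ndarray | None = None) -> np.ndarray:
    """Pixels analyzable in both maps: moderate amplitude in each
    (defaults 0.2 permille through-skull, 1.5 permille through-window),
    valid tuning in both, optionally restricted to a region of interest."""
    thr_skull, thr_window = thresholds
    mask = (np.nan_to_num(amp_skull) > thr_skull) \
        & (np.nan_to_num(amp_window) > thr_window) \
        & valid_skull & valid_window
    if region_mask is not None:
        mask &= region_mask
    return mask


def _radial_kernel(profile: SensitivityProfile, target_fwhm_mm: float,
                   pixel_pitch_mm: float) -> np.ndarray:
    """2-D convolution kernel from the simulated lateral profile, rescaled
    so its FWHM becomes ``target_fwhm_mm``, sampled on the pixel lattice and
    normalized to unit sum."""
    scale = target_fwhm_mm / profile.fwhm_mm
    offs = np.abs(profile.offsets_mm) * scale
    order = np.argsort(offs)
    r_ref, v_ref = offs[order], profile.sensitivity[order]
    r_max = r_ref[-1]
    half = int(math.ceil(r_max / pixel_pitch_mm))
    ax = np.arange(-half, half + 1) * pixel_pitch_mm
    rr = np.hypot(ax[:, None], ax[None, :])
    kern = np.interp(rr, r_ref, v_ref, right=0.0)
    total = kern.sum()
    if total <= 0:
        raise ValueError("degenerate kernel")
    return kern / total


def diffuse_map(complex_map: np.ndarray, profile: SensitivityProfile,
                target_fwhm_mm: float, pixel_pitch_mm: float) -> np.ndarray:
    """Convolve a complex tuning field with the rescaled sensitivity kernel.

    Scales at or below the pixel pitch are unresolvable on the lattice and
    return the map unchanged (delta kernel).  The kernel is normalized to
    unit sum, so a constant complex field is a fixed point.
    """
    if target_fwhm_mm <= 0:
        raise ValueError("target FWHM must be positive")
    z = np.nan_to_num(np.asarray(complex_map, dtype=complex))
    if target_fwhm_mm <= pixel_pitch_mm:
        return z.copy()
    kern = _radial_kernel(profile, target_fwhm_mm, pixel_pitch_mm)
    return fftconvolve(z, kern, mode="same")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    fstat: float


def _r2(y: np.ndarray, fitted: np.ndarray, centered: bool) -> float:
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum()) if centered else float(y @ y)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_amplitude_model(x: np.ndarray, y: np.ndarray,
                        robust: bool = True) -> LinearFit:
    """Linear model without a constant term (y = slope * x) between the two
    maps' response amplitudes; r^2 is uncentered, the convention for
    through-origin models."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    X = x[:, None]
    if robust:
        res = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
        slope = float(res.params[0])
        f = float(res.tvalues[0] ** 2)
    else:
        res = sm.OLS(y, X).fit()
        slope = float(res.params[0])
        f = float(res.fvalue)
    return LinearFit(slope, 0.0, _r2(y, slope * x, centered=False), f)


def to_octaves(freq_hz: np.ndarray, reference_hz: float = 440.0) -> np.ndarray:
    """Octaves above the reference frequency: log2(f / 440)."""
    return np.log2(np.asarray(freq_hz, dtype=float) / reference_hz)


def fit_tuning_model(x: np.ndarray, y: np.ndarray, robust: bool = True,
                     input_unit: str = "octave") -> LinearFit:
    """Linear model with intercept between the two maps' tone tunings on
    the octave scale (inputs either already in octaves, or in Hz with
    ``input_unit='hz'``)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if input_unit == "hz":
        x, y = to_octaves(x), to_octaves(y)
    elif input_unit != "octave":
        raise ValueError("input_unit must be 'octave' or 'hz'")
    X = sm.add_constant(x)
    if robust:
        res = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
        f = float(res.tvalues[1] ** 2)
    else:
        res = sm.OLS(y, X).fit()
        f = float(res.fvalue)
    intercept, slope = float(res.params[0]), float(res.params[1])
    return LinearFit(slope, intercept, _r2(y, intercept + slope * x, True), f)


@dataclass
class DiffusionScan:
    scales_mm: np.ndarray
    r2_amplitude: np.ndarray
    r2_tuning: np.ndarray
    amplitude_fits: list[LinearFit] = field(default_factory=list)
    tuning_fits: list[LinearFit] = field(default_factory=list)

    @property
    def best_scale_amplitude_mm(self) -> float:
        return float(self.scales_mm[int(np.argmax(self.r2_amplitude))])

    @property
    def best_scale_tuning_mm(self) -> float:
        return float(self.scales_mm[int(np.argmax(self.r2_tuning))])


def scan_diffusion_scales(window_complex: np.ndarray, skull_complex: np.ndarray,
                          profile: SensitivityProfile, scales_mm: np.ndarray,
                          pixel_pitch_mm: float,
                          mask: np.ndarray | None = None,
                          period_s: float | None = None,
                          robust: bool = False) -> DiffusionScan:
    """Diffuse the high-resolution (through-window) map at each scale and
    record how well it explains the through-skull map.

    Amplitude r^2 comes from the no-intercept model on |z|; tuning r^2 from
    the with-intercept model on the phase (cycle time if ``period_s`` is
    given, else radians) of candidate pixels.
    """
    window_complex = np.asarray(window_complex, dtype=complex)
    skull_complex = np.asarray(skull_complex, dtype=complex)
    if window_complex.shape != skull_complex.shape:
        raise ValueError("maps differ in geometry")
    if mask is None:
        mask = np.ones(window_complex.shape, dtype=bool)

    def phase_of(z):
        ang = np.mod(np.angle(z), 2 * np.pi)
        return ang * period_s / (2 * np.pi) if period_s else ang

    y_amp = np.abs(skull_complex)[mask]
    y_tun = phase_of(skull_complex[mask])
    scales_mm = np.asarray(scales_mm, dtype=float)
    r2a, r2t, fits_a, fits_t = [], [], [], []
    for scale in scales_mm:
        diffused = diffuse_map(window_complex, profile, scale, pixel_pitch_mm)
        fa = fit_amplitude_model(np.abs(diffused)[mask], y_amp, robust=robust)
        ft = fit_tuning_model(phase_of(diffused[mask]), y_tun, robust=robust)
        r2a.append(fa.r2)
        r2t.append(ft.r2)
        fits_a.append(fa)
        fits_t.append(ft)
    return DiffusionScan(scales_mm, np.array(r2a), np.array(r2t), fits_a, fits_t)
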