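"""Tuning-map visualization and multi-experiment landscape assembly.

The standard rendering encodes the (cyclic) tuning phase in the HSV hue
channel and the response amplitude in saturation and value, with the
amplitude at the 99th percentile of valid pixels clipped to 1 (per-subject
overrides are a RenderSpec parameter).  Composites, per-modality RGB
summaries, masking rules for tonotopy, landmark-based affine
co-registration and iso-t contours live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage
from skimage import measure

from .delay_mapping import ACCEPT_DELAY_RANGE_S
from .maps import ResponseMap, TuningMap
from .schedules import StimulusChannel
from .trial_stats import TMap

logger = logging.getLogger("wfmap")


@dataclass
class RenderSpec:
    """Amplitude scaling and hue-wheel configuration.

    ``amplitude_upper`` overrides the percentile with an absolute dR/R
    value.  ``hue_zero``/``hue_direction`` fix the wheel (default: phase 0
    maps to red, increasing phase runs through the rainbow); any cyclic
    wheel is acceptable, so the orientation is configurable rather than
    hard-coded.
    """

    percentile: float = 99.0
    amplitude_upper: float | None = None
    hue_zero: float = 0.0
    hue_direction: int = +1

    def __post_init__(self) -> None:
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.hue_direction not in (-1, +1):
            raise ValueError("hue_direction must be +1 or -1")

    def upper(self, amplitude: np.ndarray, valid: np.ndarray) -> float:
        if self.amplitude_upper is not None:
            return float(self.amplitude_upper)
        vals = amplitude[valid & np.isfinite(amplitude)]
        if vals.size == 0:
            return 1.0
        return float(np.percentile(vals, self.percentile))


def _hue(phase_s: np.ndarray, period_s: float, spec: RenderSpec) -> np.ndarray:
    return np.mod(spec.hue_zero + spec.hue_direction * phase_s / period_s, 1.0)


def render_hsv(tmap: TuningMap, spec: RenderSpec | None = None) -> np.ndarray:
    """HSV rendering: hue = tuning phase on the cyclic wheel, saturation =
    value = clipped normalized amplitude; invalid pixels get saturation 0.
    Returns an (rows, cols, 3) RGB float image in [0, 1]."""
    spec = spec or RenderSpec()
    valid = tmap.valid
    if not valid.any():
        logger.warning("render_hsv: map has no valid pixels; rendering gray")
        return np.full((*tmap.shape, 3), 0.5)
    upper = spec.upper(tmap.amplitude, valid)
    scaled = np.clip(np.nan_to_num(tmap.amplitude) / upper, 0.0, 1.0)
    h = _hue(np.nan_to_num(tmap.tuning_phase_s), tmap.period_s, spec)
    s = np.where(valid, scaled, 0.0)
    v = np.where(valid, scaled, scaled)  # invalid pixels keep gray intensity
    return hsv_to_rgb(np.stack([h, s, v], axis=-1))


def tonotopy_validity(tmap: TuningMap, tone_window_s: tuple[float, float],
                      accept_range: tuple[float, float] = ACCEPT_DELAY_RANGE_S,
                      ) -> np.ndarray:
    """Mask for tonotopy display: a pixel is valid only if its tuning phase
    falls within the tone-pip window of the trial (e.g. [2.7, 17.3] s for
    the standard sequence) and, when a per-pixel delay map exists, its delay
    lies inside the acceptable range."""
    t0, t1 = tone_window_s
    ok = tmap.valid & (tmap.tuning_phase_s >= t0) & (tmap.tuning_phase_s <= t1)
    if tmap.delay_s is not None:
        lo, hi = accept_range
        ok &= (tmap.delay_s >= lo) & (tmap.delay_s <= hi)
    return ok


def render_retinotopy_composite(polar: TuningMap, ecc: TuningMap,
                                motion: ResponseMap | TuningMap,
                                spec: RenderSpec | None = None) -> np.ndarray:
    """Combined retinotopy + motion map.

    Hue encodes polar-angle tuning, saturation the eccentricity tuning
    (center-preferring, i.e. eccentricity phase at mid-cycle, renders
    white/desaturated; periphery-preferring renders fully saturated), and
    value the motion-response amplitude.
    """
    if polar.shape != ecc.shape or polar.shape != motion.shape:
        raise ValueError("maps differ in geometry")
    spec = spec or RenderSpec()
    h = _hue(polar.tuning_phase_s, polar.period_s, spec)
    # circular distance of eccentricity phase from mid-cycle (= center zone)
    T = ecc.period_s
    d = np.abs(np.mod(ecc.tuning_phase_s - T / 2, T))
    d = np.minimum(d, T - d)
    s = np.clip(d / (T / 2), 0.0, 1.0)
    amp = motion.amplitude
    valid = getattr(motion, "valid", np.isfinite(amp))
    upper = spec.upper(amp, valid)
    v = np.clip(np.nan_to_num(amp) / upper, 0.0, 1.0)
    return hsv_to_rgb(np.stack([h, np.where(valid, s, 0.0), v], axis=-1))


def render_rgb_summary(maps: list[TuningMap], channels: list[StimulusChannel],
                       tolerance_s: float = 1.0,
                       spec: RenderSpec | None = None) -> np.ndarray:
    """Multi-frequency summary: each channel's map goes to one RGB plane.

    Per channel, only pixels whose tuning phase falls within the
    most-intense-stimulus window of that channel's cycle, widened by
    ``tolerance_s`` on either side, contribute; their scaled amplitude is
    written into the channel's color plane.
    """
    if len(maps) > 3:
        raise ValueError("RGB summary supports at most 3 channels")
    if len(maps) != len(channels):
        raise ValueError("need one channel per map")
    spec = spec or RenderSpec()
    shape = maps[0].shape
    out = np.zeros((*shape, 3))
    for plane, (tmap, ch) in enumerate(zip(maps, channels)):
        if tmap.shape != shape:
            raise ValueError("maps differ in geometry")
        w0, w1 = ch.peak_window()
        mask = (tmap.valid
                & (tmap.tuning_phase_s >= w0 - tolerance_s)
                & (tmap.tuning_phase_s <= w1 + tolerance_s))
        upper = spec.upper(tmap.amplitude, tmap.valid)
        scaled = np.clip(np.nan_to_num(tmap.amplitude) / upper, 0.0, 1.0)
        out[..., plane] = np.where(mask, scaled, 0.0)
    return out


# ---------------------------------------------------------------------------
# landscape assembly


@dataclass
class AffineTransform2D:
    """2x3 matrix mapping source (row, col) to destination (row, col)."""

    matrix: np.ndarray  # (2, 3)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("linear part is singular")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform2D":
        A = self.matrix[:, :2]
        b = self.matrix[:, 2]
        Ai = np.linalg.inv(A)
        return AffineTransform2D(np.hstack([Ai, (-Ai @ b)[:, None]]))


def estimate_affine(landmarks_src: np.ndarray, landmarks_dst: np.ndarray
                    ) -> AffineTransform2D:
    """Least-squares affine from >= 3 non-collinear landmark pairs
    ((row, col) coordinates)."""
    src = np.atleast_2d(np.asarray(landmarks_src, dtype=float))
    dst = np.atleast_2d(np.asarray(landmarks_dst, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need at least 3 matched landmark pairs")
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; affine is underdetermined")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform2D(coef.T)


def apply_affine(image: np.ndarray, transform: AffineTransform2D,
                 target_shape: tuple[int, int], is_mask: bool = False
                 ) -> np.ndarray:
    """Resample a scalar plane (bilinear) or mask (nearest) into the target
    geometry. NaNs in scalar planes stay NaN where they dominate."""
    inv = transform.inverse().matrix
    order = 0 if is_mask else 1
    arr = image.astype(float)
    out = ndimage.affine_transform(arr, inv[:, :2], offset=inv[:, 2],
                                   output_shape=target_shape, order=order,
                                   mode="constant", cval=np.nan)
    if is_mask:
        return np.nan_to_num(out, nan=0.0) > 0.5
    return out


def iso_t_contours(tmap: TMap | np.ndarray, levels: list[float]
                   ) -> dict[float, list[np.ndarray]]:
    """Marching-squares iso-contours of a t map at the given levels.

    Returns ``{level: [polyline (N, 2) arrays in (row, col)]}``; levels above
    the map maximum yield empty lists, NaN pixels are treated as below every
    level.
    """
    t = tmap.t if isinstance(tmap, TMap) else np.asarray(tmap, dtype=float)
    finite = t[np.isfinite(t)]
    fill = (finite.min() - 1.0) if finite.size else 0.0
    field2d = np.where(np.isfinite(t), t, fill)
    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        if field2d.max() <= level or field2d.min() >= level:
            out[level] = []
        else:
            out[level] = measure.find_contours(field2d, level)
    return out
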