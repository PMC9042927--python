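"""Movie containers, normalization, binning, and on-disk formats.

Wide-field intrinsic-signal recordings are 3-D stacks (time x rows x cols)
of backscattered-light intensity.  Analysis operates on the relative change
against a baseline, dR/R, which in vivo is at the permille scale.  Movies
are stored as multi-page grayscale TIFF or ``.npy``/``.npz`` arrays with a
JSON sidecar carrying the acquisition metadata (frame rate, wavelength),
since the raw stacks themselves are unit- and rate-agnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

from .schedules import StimulusChannel

logger = logging.getLogger("wfmap")

MovieKind = Literal["raw", "relative"]

#: sanity bound for |dR/R|; real intrinsic signals are permille-scale, so
#: anything beyond 20% indicates a unit error upstream.
RELATIVE_SANITY_BOUND = 0.2


@dataclass
class Movie:
    """A wide-field recording: ``frames[t, row, col]`` at ``frame_rate_hz``.

    ``kind`` distinguishes raw intensity (arbitrary camera units) from the
    dimensionless relative change dR/R.  Invalid pixels (e.g. zero-baseline
    pixels after normalization) are NaN and propagate through downstream
    maps rather than raising.
    """

    frames: np.ndarray
    frame_rate_hz: float
    kind: MovieKind = "raw"
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, row, col), got shape {self.frames.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.kind == "relative":
            finite = self.frames[np.isfinite(self.frames)]
            if finite.size and np.abs(finite).max() >= RELATIVE_SANITY_BOUND:
                raise ValueError(
                    "relative movie contains |dR/R| >= "
                    f"{RELATIVE_SANITY_BOUND}; intrinsic signals are permille-scale"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Frame timestamps at frame centers, seconds from session start."""
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate_hz


@dataclass
class SessionConfig:
    """Acquisition + stimulus-timing description of one recording session.

    Every channel's cycle period must divide the session duration exactly so
    that each stimulus frequency lands on an exact spectral bin.
    """

    wavelength_nm: float
    frame_rate_hz: float
    duration_s: float
    channels: list[StimulusChannel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ch in self.channels:
            n = self.duration_s / ch.cycle_period_s
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(
                    f"channel {ch.label!r}: duration {self.duration_s} s is not an "
                    f"integer multiple of cycle period {ch.cycle_period_s} s"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "frame_rate_hz": self.frame_rate_hz,
            "duration_s": self.duration_s,
            "channels": [ch.to_dict() for ch in self.channels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        channels = [StimulusChannel.from_dict(c) for c in d.get("channels", [])]
        return cls(
            wavelength_nm=d["wavelength_nm"],
            frame_rate_hz=d["frame_rate_hz"],
            duration_s=d["duration_s"],
            channels=channels,
        )


# ---------------------------------------------------------------------------
# normalization


def to_relative(
    movie: Movie,
    baseline_mode: Literal["session_mean", "prestim_mean", "trial_max"] = "session_mean",
    window: tuple[float, float] | None = None,
) -> Movie:
    """Convert a raw-intensity movie to relative change dR/R.

    Per pixel, ``out(t) = (raw(t) - B) / B`` with the baseline ``B`` chosen by
    ``baseline_mode``:

    - ``session_mean``: temporal mean over the whole session (the Fourier
      analysis convention),
    - ``prestim_mean``: temporal mean over ``window`` (seconds), the
      pre-stimulus interval of a trial,
    - ``trial_max``: the temporal maximum (so dR/R <= 0 everywhere).

    Pixels whose baseline is zero or negative cannot be normalized and are
    masked NaN instead of raising.
    """
    if movie.kind != "raw":
        raise ValueError("to_relative expects a raw-intensity movie")
    frames = movie.frames
    if baseline_mode == "session_mean":
        baseline = frames.mean(axis=0)
    elif baseline_mode == "prestim_mean":
        if window is None:
            raise ValueError("prestim_mean requires a (start_s, end_s) window")
        t = movie.times_s
        sel = (t >= window[0]) & (t < window[1])
        if not sel.any():
            raise ValueError(f"window {window} contains no frames")
        baseline = frames[sel].mean(axis=0)
    elif baseline_mode == "trial_max":
        baseline = frames.max(axis=0)
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")

    invalid = ~(baseline > 0)
    if invalid.any():
        logger.warning("to_relative: %d pixels with non-positive baseline masked", invalid.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (frames - baseline) / baseline
    rel[:, invalid] = np.nan
    return Movie(rel, movie.frame_rate_hz, kind="relative", wavelength_nm=movie.wavelength_nm)


def bin_movie(movie: Movie, spatial_factor: int = 1, temporal_factor: int = 1) -> Movie:
    """Block-mean binning in space and time.

    The acquisition stream (e.g. 1920x1200 @ 80 fps) is reduced to the saved
    format (480x300 @ 5 fps) with factors (4, 16).  Block means keep dR/R
    values on the same scale and conserve the global mean exactly.
    """
    t, h, w = movie.shape
    if temporal_factor < 1 or spatial_factor < 1:
        raise ValueError("binning factors must be >= 1")
    if t % temporal_factor:
        raise ValueError(f"time axis ({t} frames) not divisible by temporal_factor {temporal_factor}")
    if h % spatial_factor:
        raise ValueError(f"row axis ({h} px) not divisible by spatial_factor {spatial_factor}")
    if w % spatial_factor:
        raise ValueError(f"col axis ({w} px) not divisible by spatial_factor {spatial_factor}")
    out = movie.frames.reshape(
        t // temporal_factor, temporal_factor, h // spatial_factor, spatial_factor,
        w // spatial_factor, spatial_factor,
    ).mean(axis=(1, 3, 5))
    return Movie(out, movie.frame_rate_hz / temporal_factor, kind=movie.kind,
                 wavelength_nm=movie.wavelength_nm)


def sem_trace(cycle_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SEM across repeated cycles, per time point.

    ``cycle_stack`` is (n_cycles, time[, ...]).  The SEM is computed as
    sqrt((E[X^2] - E[X]^2) / n) — i.e. the *biased* (divide-by-n) standard
    deviation divided by sqrt(n).  This is the convention used for the
    published traces; it differs from the n-1 sample convention (see
    docs/methods.md) and notably yields SEM 0 at n = 1.
    """
    cycle_stack = np.asarray(cycle_stack, dtype=float)
    n = cycle_stack.shape[0]
    if n < 1:
        raise ValueError("need at least one cycle")
    mean = cycle_stack.mean(axis=0)
    ex2 = (cycle_stack**2).mean(axis=0)
    var = np.maximum(ex2 - mean**2, 0.0)  # clip tiny negative rounding
    return mean, np.sqrt(var / n)


def fold_cycles(movie: Movie, cycle_period_s: float) -> np.ndarray:
    """Reshape a movie into (n_cycles, frames_per_cycle, rows, cols)."""
    fpc = cycle_period_s * movie.frame_rate_hz
    if abs(fpc - round(fpc)) > 1e-9:
        raise ValueError("cycle period is not an integer number of frames")
    fpc = int(round(fpc))
    if movie.n_frames % fpc:
        raise ValueError("movie length is not an integer number of cycles")
    return movie.frames.reshape(movie.n_frames // fpc, fpc, *movie.shape[1:])


# ---------------------------------------------------------------------------
# on-disk formats


def save_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as multi-page TIFF (float32) or .npy/.npz (float64),
    with a JSON sidecar (``<stem>.json``) for frame rate and wavelength."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, movie.frames.astype(np.float32),
                         photometric="minisblack")
    elif path.suffix == ".npy":
        np.save(path, movie.frames)
    elif path.suffix == ".npz":
        np.savez_compressed(path, frames=movie.frames)
    else:
        raise ValueError(f"unsupported movie container {path.suffix!r}")
    sidecar = {
        "frame_rate_hz": movie.frame_rate_hz,
        "kind": movie.kind,
        "wavelength_nm": movie.wavelength_nm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_movie(path: str | Path) -> Movie:
    """Read a movie saved by :func:`save_movie` (sidecar JSON required)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if path.suffix.lower() in {".tif", ".tiff"}:
        frames = tifffile.imread(path)
    elif path.suffix == ".npy":
        frames = np.load(path)
    elif path.suffix == ".npz":
        frames = np.load(path)["frames"]
    else:
        raise ValueError(f"unsupported movie container {path.suffix!r}")
    return Movie(np.asarray(frames, dtype=float), sidecar["frame_rate_hz"],
                 kind=sidecar.get("kind", "raw"),
                 wavelength_nm=sidecar.get("wavelength_nm"))


def save_session_config(path: str | Path, config: SessionConfig) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=1))


def load_session_config(path: str | Path) -> SessionConfig:
    return SessionConfig.from_dict(json.loads(Path(path).read_text()))
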