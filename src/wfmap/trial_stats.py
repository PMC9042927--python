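"""Trial-based category analysis: baseline normalization, response-window
quantification, pixelwise Welch t maps and the face-vs-other differential.

Category experiments (e.g. face-patch mapping) present randomized 20 s
trials rather than periodic cycles.  Each trial trace is normalized to its
own pre-stimulus baseline (first 2 s), polarity-compensated, and summarized
by the mean dR/R in a response window 4-10 s after the first stimulus
frame.  Category contrasts use the Welch t statistic with sample (n-1)
standard deviations; no p-values are attached — at the trial counts used
here (n > 100), t > 2.0 and t > 3.4 correspond to two-tailed p < 0.05 and
p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging_io import Movie


@dataclass
class TrialSet:
    """Baseline-normalized, polarity-compensated trial responses.

    ``data`` is (n_trials, n_frames_per_trial, rows, cols) of dR/R; windows
    are in seconds, the response window relative to ``stim_onset_s`` (the
    first stimulus frame), the baseline window relative to trial start.
    """

    data: np.ndarray
    frame_rate_hz: float
    baseline_window_s: tuple[float, float] = (0.0, 2.0)
    stim_onset_s: float = 2.0
    response_window_s: tuple[float, float] = (4.0, 10.0)
    category: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("trial data must be 4-D (trial, time, row, col)")
        if self.baseline_window_s[1] > self.stim_onset_s + 1e-9:
            raise ValueError("baseline window must precede stimulus onset")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def trial_duration_s(self) -> float:
        return self.data.shape[1] / self.frame_rate_hz


def normalize_trials(movie: Movie, trial_onsets_s: Sequence[float],
                     trial_duration_s: float,
                     baseline_window_s: tuple[float, float] = (0.0, 2.0),
                     stim_onset_s: float = 2.0,
                     response_window_s: tuple[float, float] = (4.0, 10.0),
                     polarity: int = -1, category: str = "") -> TrialSet:
    """Cut trials from a raw movie and normalize each to its baseline.

    Per trial and pixel the trace becomes ``(raw - B)/B`` with ``B`` the
    mean over the pre-stimulus baseline window, then multiplied by the
    wavelength polarity so that a response reads positive.  Trials must not
    overlap or extend past the movie end.
    """
    onsets = np.asarray(sorted(trial_onsets_s), dtype=float)
    if onsets.size == 0:
        raise ValueError("no trials")
    if np.any(np.diff(onsets) < trial_duration_s - 1e-9):
        raise ValueError("trials overlap")
    fs = movie.frame_rate_hz
    n_tf = int(round(trial_duration_s * fs))
    frames = movie.frames
    trials = []
    for onset in onsets:
        i0 = int(round(onset * fs))
        if i0 < 0 or i0 + n_tf > movie.n_frames:
            raise ValueError(f"trial at {onset} s extends past the movie")
        trials.append(frames[i0:i0 + n_tf])
    data = np.stack(trials)
    t = (np.arange(n_tf) + 0.5) / fs
    bsel = (t >= baseline_window_s[0]) & (t < baseline_window_s[1])
    if not bsel.any():
        raise ValueError("baseline window contains no frames")
    baseline = data[:, bsel].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = (data - baseline) / baseline
    norm[np.broadcast_to(~(baseline > 0), norm.shape)] = np.nan
    return TrialSet(polarity * norm, fs, baseline_window_s, stim_onset_s,
                    response_window_s, category)


def trial_sets_from_table(movie: Movie, trial_table: pd.DataFrame,
                          trial_duration_s: float, polarity: int = -1,
                          **kwargs) -> dict[str, TrialSet]:
    """Split a session into per-category TrialSets using a trial table with
    ``onset_s`` and ``category`` columns (CSV-friendly)."""
    out = {}
    for category, grp in trial_table.groupby("category"):
        out[str(category)] = normalize_trials(
            movie, grp["onset_s"].to_numpy(), trial_duration_s,
            polarity=polarity, category=str(category), **kwargs)
    return out


def trial_response_values(trial_set: TrialSet) -> np.ndarray:
    """Per-trial, per-pixel scalar response: the mean dR/R over the response
    window (relative to the first stimulus frame onset)."""
    w0, w1 = trial_set.response_window_s
    t = (np.arange(trial_set.data.shape[1]) + 0.5) / trial_set.frame_rate_hz
    lo = trial_set.stim_onset_s + w0
    hi = trial_set.stim_onset_s + w1
    if hi > trial_set.trial_duration_s + 1e-9:
        raise ValueError("response window extends past the trial")
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("response window contains no frames")
    return trial_set.data[:, sel].mean(axis=1)


@dataclass
class TMap:
    """Pixelwise Welch t values with the group sizes that produced them."""

    t: np.ndarray
    n1: int
    n2: int


def welch_t_map(group_a: np.ndarray, group_b: np.ndarray) -> TMap:
    """Welch's t statistic per pixel:
    ``t = (mean_a - mean_b) / sqrt(s_a^2/N_a + s_b^2/N_b)`` with sample
    (n-1) standard deviations.  Pixels with zero pooled variance are masked
    NaN.  Group arrays are (n_trials, ...pixels)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 trials")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    denom = np.sqrt(va / n1 + vb / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    t = np.where(denom > 0, t, np.nan)
    return TMap(t, n1, n2)


def differential_map(category_means: Mapping[str, np.ndarray],
                     target: str = "face") -> np.ndarray:
    """Target-category mean response minus the maximum of all other
    categories' mean responses, per pixel; positive where the target (e.g.
    faces) beats every control category."""
    if target not in category_means:
        raise KeyError(f"no category {target!r}")
    others = [v for k, v in category_means.items() if k != target]
    if not others:
        raise ValueError("need at least 2 categories")
    return np.asarray(category_means[target]) - np.max(np.stack(others), axis=0)
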