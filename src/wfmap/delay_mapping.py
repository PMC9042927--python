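"""Hemodynamic-delay cancellation from temporally mirrored session pairs.

A pixel's raw response phase confounds its stimulus preference ``s`` with
the hemodynamic delay ``delta``: in the forward session the response peaks
at ``(s + delta) mod T``, and in the time-reversed session (downward tone
sequence, counterclockwise sweep) the same stimulus arrives at ``T - s``,
so the response peaks at ``(T - s + delta) mod T``.  Assuming the delay is
identical across the mirrored pair, summing the two raw phases cancels
``s`` and leaves ``2*delta (mod T)`` — the basis of the per-pixel delay and
tuning estimates here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import ResponseMap, TuningMap

#: empirically acceptable hemodynamic-delay range (s), inclusive
ACCEPT_DELAY_RANGE_S = (2.0, 5.7)


def combine_reversed_sessions(fwd: ResponseMap, rev: ResponseMap,
                              accept_range: tuple[float, float] | None = None,
                              ) -> TuningMap:
    """Disentangle tuning phase and hemodynamic delay per pixel.

    ``delta0 = ((phi_fwd + phi_rev) mod T) / 2`` lies in [0, T/2); the pair
    ``{delta0, delta0 + T/2}`` is both consistent with the data, and the
    candidate inside the physiologic window [0, T/2) — ``delta0`` itself —
    is chosen (for T ~ 20 s this window is [0, 10) s, far above plausible
    delays).  If ``accept_range`` is given it acts as a stronger
    disambiguator: when ``delta0`` is outside the range but
    ``delta0 + T/2`` is inside, the latter is taken.  The tuning phase is
    ``(phi_fwd - delta) mod T`` on the forward timeline, and the amplitude
    is the mean of the two sessions' amplitudes.
    """
    if fwd.shape != rev.shape:
        raise ValueError("session maps differ in geometry")
    if abs(fwd.period_s - rev.period_s) > 1e-9:
        raise ValueError("session maps differ in cycle period")
    if not (fwd.polarity_compensated and rev.polarity_compensated):
        raise ValueError("compensate polarity before combining sessions")
    T = fwd.period_s
    delta = np.mod(fwd.phase_time_s + rev.phase_time_s, T) / 2.0
    if accept_range is not None:
        lo, hi = accept_range
        alt = delta + T / 2
        out = ~((delta >= lo) & (delta <= hi)) & (alt >= lo) & (alt <= hi)
        delta = np.where(out, alt, delta)
    tuning = np.mod(fwd.phase_time_s - delta, T)
    amplitude = 0.5 * (fwd.amplitude + rev.amplitude)
    valid = fwd.valid & rev.valid
    return TuningMap(tuning, amplitude, T, delay_s=delta, valid=valid,
                     label=fwd.label or rev.label)


def select_candidates(tmap: TuningMap, fraction: float = 0.10) -> np.ndarray:
    """Mask of the top-amplitude valid pixels.

    Selects ``ceil(fraction * n_valid)`` pixels ranked by amplitude; ties
    are broken deterministically by row-major pixel order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    valid = tmap.valid
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("map has no valid pixels")
    k = int(np.ceil(fraction * n_valid))
    amp = np.where(valid, tmap.amplitude, -np.inf).ravel()
    # stable sort on -amp keeps row-major order within ties
    order = np.argsort(-amp, kind="stable")[:k]
    mask = np.zeros(amp.size, dtype=bool)
    mask[order] = True
    return mask.reshape(tmap.shape)


@dataclass
class DelaySummary:
    mean_s: float
    n_in_range: int
    n_candidates: int
    hist_counts: np.ndarray
    hist_edges_s: np.ndarray


def summarize_delay(delays_s: np.ndarray, mask: np.ndarray | None = None,
                    accept_range: tuple[float, float] = ACCEPT_DELAY_RANGE_S,
                    n_bins: int = 40) -> DelaySummary:
    """Mean hemodynamic delay over candidate pixels inside the acceptance
    range (closed interval), plus the delay histogram of all candidates.

    Raises if no candidate falls in range; the error message carries the
    histogram so the failure is diagnosable.
    """
    delays_s = np.asarray(delays_s, dtype=float)
    vals = delays_s[mask] if mask is not None else delays_s.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no candidate delays")
    lo, hi = accept_range
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, max(hi * 2, vals.max())))
    in_range = vals[(vals >= lo) & (vals <= hi)]
    if in_range.size == 0:
        raise ValueError(
            f"no candidate delay within [{lo}, {hi}] s; histogram counts "
            f"(edges {edges[0]:.1f}..{edges[-1]:.1f} s): {counts.tolist()}"
        )
    return DelaySummary(float(in_range.mean()), in_range.size, vals.size,
                        counts, edges)
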