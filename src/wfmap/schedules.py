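"""Stimulus-timing objects for phase-encoded mapping experiments.

Each experiment locks one stimulus dimension to a repeating cycle so the
preferred stimulus of a pixel can be read out as the phase of its response
at the cycle frequency.  The schedule objects built here serve double duty:
they are the ground truth for the synthetic-movie generator and the decoding
reference for the analysis (which stimulus was on at a given cycle time).

Stimulus "level" is an abstract per-channel scalar — a tone frequency in Hz,
a polar angle in degrees, an eccentricity band in degrees, a puff target —
because actual audio/visual rendering is out of scope.  Polar angles are in
degrees clockwise from 12 o'clock as seen by the subject (the convention is
ours; published maps define it only pictorially).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

SweepKind = Literal["eccentricity", "polar_cw", "polar_ccw"]


@dataclass
class StimulusEvent:
    """One stimulus presentation within a cycle.

    ``weight`` marks stimulus intensity so summary renderings can locate the
    most-intense-stimulus window generically (1.0 = peak intensity).
    """

    onset_s: float
    duration_s: float
    level: float
    weight: float = 1.0


@dataclass
class StimulusChannel:
    """A periodically repeating stimulus stream within a session."""

    label: str
    cycle_period_s: float
    n_cycles: int
    events: list[StimulusEvent] = field(default_factory=list)
    sweep: SweepKind | None = None

    def __post_init__(self) -> None:
        if self.cycle_period_s <= 0:
            raise ValueError("cycle period must be positive")
        for ev in self.events:
            if ev.onset_s + ev.duration_s > self.cycle_period_s + 1e-9:
                raise ValueError(
                    f"channel {self.label!r}: event at {ev.onset_s} s with duration "
                    f"{ev.duration_s} s exceeds the {self.cycle_period_s} s cycle"
                )

    @property
    def duration_s(self) -> float:
        return self.cycle_period_s * self.n_cycles

    @property
    def frequency_hz(self) -> float:
        return 1.0 / self.cycle_period_s

    def level_at(self, t_in_cycle: float):
        """Stimulus level at a cycle time: the swept parameter for sweep
        channels, the active event's level otherwise (None in silence).

        For ``polar_cw``/``polar_ccw`` the level is the polar angle in degrees
        clockwise from 12 o'clock (both sweeps start at 0 deg); for
        ``eccentricity`` it is the ``(inner, outer)`` radius pair in degrees
        of the zone containing moving dots, cosine-modulated from the
        (5, 15) deg periphery at cycle start to the (0, 5) deg center at
        mid-cycle.
        """
        t = t_in_cycle % self.cycle_period_s
        if self.sweep == "polar_cw":
            return (360.0 * t / self.cycle_period_s) % 360.0
        if self.sweep == "polar_ccw":
            return (-360.0 * t / self.cycle_period_s) % 360.0
        if self.sweep == "eccentricity":
            c = math.cos(2 * math.pi * t / self.cycle_period_s)
            outer = 10.0 + 5.0 * c
            inner = 2.5 + 2.5 * c
            return (inner, outer)
        for ev in self.events:
            if ev.onset_s <= t < ev.onset_s + ev.duration_s:
                return ev.level
        return None

    def peak_window(self) -> tuple[float, float]:
        """(start, end) cycle times spanning the most intense events."""
        if not self.events:
            raise ValueError(f"channel {self.label!r} has no events")
        wmax = max(ev.weight for ev in self.events)
        peak = [ev for ev in self.events if ev.weight >= wmax - 1e-12]
        return (min(ev.onset_s for ev in peak),
                max(ev.onset_s + ev.duration_s for ev in peak))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "cycle_period_s": self.cycle_period_s,
            "n_cycles": self.n_cycles,
            "sweep": self.sweep,
            "events": [[e.onset_s, e.duration_s, e.level, e.weight] for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusChannel":
        events = [StimulusEvent(*e) for e in d.get("events", [])]
        return cls(d["label"], d["cycle_period_s"], d["n_cycles"],
                   events=events, sweep=d.get("sweep"))


@dataclass
class ToneSequence:
    """A geometric semitone pip sequence: pip k has frequency
    ``start_hz * 2**(k * step_semitones / 12)``."""

    start_hz: float
    n_pips: int
    step_semitones: int
    pip_duration_s: float
    pre_silence_s: float
    post_silence_s: float

    def __post_init__(self) -> None:
        if self.start_hz <= 0:
            raise ValueError("start frequency must be positive")
        if self.n_pips < 1:
            raise ValueError("need at least one pip")

    @property
    def frequencies_hz(self) -> np.ndarray:
        k = np.arange(self.n_pips)
        return self.start_hz * 2.0 ** (k * self.step_semitones / 12.0)

    @property
    def final_hz(self) -> float:
        return float(self.frequencies_hz[-1])

    @property
    def pip_center_times_s(self) -> np.ndarray:
        k = np.arange(self.n_pips)
        return self.pre_silence_s + k * self.pip_duration_s + self.pip_duration_s / 2

    @property
    def trial_duration_s(self) -> float:
        return self.pre_silence_s + self.n_pips * self.pip_duration_s + self.post_silence_s

    @property
    def tone_window_s(self) -> tuple[float, float]:
        """Cycle-time span during which tones (not silence) are playing."""
        return (self.pre_silence_s, self.pre_silence_s + self.n_pips * self.pip_duration_s)

    def center_time_of(self, freq_hz: float) -> float:
        """Cycle time of the pip center closest to ``freq_hz`` (exact for
        frequencies on the semitone grid)."""
        k = 12.0 * math.log2(freq_hz / self.start_hz) / self.step_semitones
        ki = int(round(k))
        if not 0 <= ki < self.n_pips:
            raise ValueError(f"{freq_hz} Hz is outside the sequence")
        return float(self.pip_center_times_s[ki])

    def frequency_at(self, t_in_cycle: float) -> float | None:
        """Pip frequency playing at a cycle time, None during silence."""
        t0, t1 = self.tone_window_s
        if not (t0 <= t_in_cycle < t1):
            return None
        k = int((t_in_cycle - t0) / self.pip_duration_s)
        return float(self.frequencies_hz[min(k, self.n_pips - 1)])

    def to_channel(self, n_cycles: int = 20, label: str = "tones") -> StimulusChannel:
        events = [
            StimulusEvent(self.pre_silence_s + k * self.pip_duration_s,
                          self.pip_duration_s, float(f))
            for k, f in enumerate(self.frequencies_hz)
        ]
        return StimulusChannel(label, self.trial_duration_s, n_cycles, events=events)


def build_tone_sequence(start_hz: float, n_pips: int, step_semitones: int,
                        pip_duration_s: float = 0.2, pre_silence_s: float = 2.7,
                        post_silence_s: float = 2.7) -> ToneSequence:
    """Build a semitone pip sequence (see :class:`ToneSequence`)."""
    return ToneSequence(start_hz, n_pips, step_semitones, pip_duration_s,
                        pre_silence_s, post_silence_s)


def tonotopy_sequence(direction: Literal["up", "down"] = "up") -> ToneSequence:
    """The standard tonotopy trial: 2.7 s silence, 73 pips x 0.2 s spanning
    440 Hz to 28,160 Hz (6 octaves) in semitone steps, 2.7 s silence = 20 s."""
    if direction == "up":
        return build_tone_sequence(440.0, 73, +1)
    if direction == "down":
        return build_tone_sequence(28160.0, 73, -1)
    raise ValueError(f"unknown direction {direction!r}")


def build_parcellation_schedule(
    periods_s: Sequence[float],
    n_cycles: Sequence[int],
    event_specs: Sequence[tuple[str, float]] | None = None,
) -> list[StimulusChannel]:
    """Channels for a simultaneous multi-frequency session.

    Each channel repeats with its own cycle period; all products
    ``period * count`` must agree on a single session duration so that each
    stimulus frequency is an exact spectral bin.  ``event_specs`` is a list of
    ``(label, event_duration_s)``; each event is centered in its cycle (the
    air-puff and noise-burst trains are presented at mid-cycle, and the
    dot-speed ramp peaks at mid-cycle).
    """
    if len(periods_s) != len(n_cycles):
        raise ValueError("periods and counts must align")
    durations = [p * n for p, n in zip(periods_s, n_cycles)]
    if max(durations) - min(durations) > 1e-9:
        detail = ", ".join(f"{p} s x {n} = {d} s" for p, n, d in zip(periods_s, n_cycles, durations))
        raise ValueError(f"channels disagree on session duration: {detail}")
    if event_specs is None:
        event_specs = [(f"ch{i}", min(periods_s) / 3) for i in range(len(periods_s))]
    if len(event_specs) != len(periods_s):
        raise ValueError("event_specs must align with periods")
    channels = []
    for (label, ev_dur), period, count in zip(event_specs, periods_s, n_cycles):
        onset = (period - ev_dur) / 2
        channels.append(StimulusChannel(label, period, count,
                                        events=[StimulusEvent(onset, ev_dur, 1.0)]))
    return channels


def parcellation_channels() -> list[StimulusChannel]:
    """The three-modality parcellation session (396 s): somatosensory
    air-puff train (6 s, 22 s cycle x 18), auditory noise bursts (9.8 s,
    19.8 s cycle x 20), and visual moving dots at peak speed for 4 s
    mid-cycle (18 s cycle x 22)."""
    return build_parcellation_schedule(
        periods_s=(22.0, 19.8, 18.0),
        n_cycles=(18, 20, 22),
        event_specs=[("som", 6.0), ("aud", 9.8), ("vis", 4.0)],
    )


def somatotopy_channels() -> list[StimulusChannel]:
    """The two-nozzle somatotopy session (437 s): oral puff train (4 s, 23 s
    cycle x 19) and facial puff train (4 s, 19 s cycle x 23)."""
    return build_parcellation_schedule(
        periods_s=(23.0, 19.0),
        n_cycles=(19, 23),
        event_specs=[("oral", 4.0), ("facial", 4.0)],
    )


def build_sweep_schedule(kind: SweepKind, cycle_period_s: float = 20.0,
                         n_cycles: int = 20) -> StimulusChannel:
    """A retinotopy sweep channel.

    ``polar_cw``/``polar_ccw``: a quarter-circle zone of radially moving dots
    whose middle line starts at 12 o'clock and sweeps a full round per cycle
    (0.05 rounds/s at the 20 s default).  ``eccentricity``: the moving-dot
    zone contracts from the (5-15) deg periphery to the (0-5) deg center and
    back, cosine-modulated over the cycle.  The swept parameter is exposed by
    :meth:`StimulusChannel.level_at`.
    """
    if kind not in ("eccentricity", "polar_cw", "polar_ccw"):
        raise ValueError(f"unknown sweep kind {kind!r}")
    if cycle_period_s <= 0:
        raise ValueError("cycle period must be positive")
    return StimulusChannel(kind, cycle_period_s, n_cycles, sweep=kind)
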