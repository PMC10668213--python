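"""Stimulation pulse-train construction and triggering.

A stimulation is a unipolar TTL pulse train defined by frequency, total
duration and duty cycle: the train contains ``floor(frequency * duration)``
complete cycles of length ``1/frequency`` seconds, each high for
``duty_cycle/100`` of its length starting at cycle onset.  Partial trailing
cycles are dropped.  The physical stimulus isolator converts the unipolar
train into a charge-balanced bipolar stimulus; :func:`to_bipolar` models that
conversion as a symmetric biphasic split of each pulse.

Automatic triggering watches a sampled TTL input line and launches one train
per selected edge (rising or falling), with a lockout equal to the train
duration so re-triggers during an ongoing train are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "StimParams",
    "PulseTrain",
    "StimCounters",
    "build_pulse_train",
    "on_trigger",
    "to_bipolar",
]


@dataclass(frozen=True)
class StimParams:
    """Pulse-train definition.

    frequency : Hz, > 0
    duration : seconds, > 0 (total train length)
    duty_cycle : percent in (0, 100], fraction of each cycle held high
    polarity : "unipolar" (TTL, e.g. optogenetic laser gate) or "bipolar"
        (via the stimulus isolator)
    trigger_edge : which edge of the external TTL input launches a train
    dwell_delay : seconds the animal must remain in a rewarded zone before an
        animal-triggered stimulation; mirrored here for standalone use, the
        maze engine owns the gating
    """

    frequency: float
    duration: float
    duty_cycle: float = 50.0
    polarity: str = "bipolar"
    trigger_edge: str = "rising"
    dwell_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (0 < self.duty_cycle <= 100):
            raise ValueError(f"duty_cycle must be in (0, 100], got {self.duty_cycle}")
        if self.polarity not in ("unipolar", "bipolar"):
            raise ValueError(f"polarity must be unipolar|bipolar, got {self.polarity!r}")
        if self.trigger_edge not in ("rising", "falling"):
            raise ValueError(
                f"trigger_edge must be rising|falling, got {self.trigger_edge!r}"
            )
        if self.dwell_delay < 0:
            raise ValueError(f"dwell_delay must be >= 0, got {self.dwell_delay}")


@dataclass(frozen=True)
class PulseTrain:
    """High intervals of a unipolar train, relative to train onset."""

    intervals: tuple[tuple[float, float], ...]
    total_duration: float

    @property
    def n_pulses(self) -> int:
        return len(self.intervals)

    def total_high_time(self) -> float:
        return sum(b - a for a, b in self.intervals)


def build_pulse_train(p: StimParams) -> PulseTrain:
    """Construct the pulse train for ``p``; requires at least one full cycle."""
    n = math.floor(p.frequency * p.duration)
    if n < 1:
        raise ValueError(
            f"frequency*duration = {p.frequency * p.duration:g} < 1: "
            "train shorter than one cycle"
        )
    cycle = 1.0 / p.frequency
    high = cycle * p.duty_cycle / 100.0
    if p.duty_cycle == 100.0:
        # contiguous cycles coalesce into one high span
        intervals = ((0.0, n * cycle),)
    else:
        intervals = tuple((k * cycle, k * cycle + high) for k in range(n))
    return PulseTrain(intervals=intervals, total_duration=p.duration)


def on_trigger(line_history: list[tuple[float, int]], p: StimParams) -> list[float]:
    """Stimulation onset times for a sampled TTL input.

    ``line_history`` is a time-ordered list of ``(t, level)`` samples of the
    external trigger line.  One train is scheduled per selected edge; edges
    arriving while a train is still running (within ``p.duration`` of the last
    onset) are ignored.
    """
    want = (0, 1) if p.trigger_edge == "rising" else (1, 0)
    onsets: list[float] = []
    prev_level = None
    for t, level in line_history:
        level = 1 if level else 0
        if prev_level is not None and (prev_level, level) == want:
            if not onsets or t - onsets[-1] >= p.duration:
                onsets.append(t)
        prev_level = level
    return onsets


def to_bipolar(train: PulseTrain) -> list[tuple[float, float, int]]:
    """Model the isolator's bipolar conversion of a unipolar train.

    Each high interval is split at its midpoint into a positive then an equal
    negative half-phase, so the signed waveform integrates to zero (charge
    balance).  Returns ``(t_start, t_end, sign)`` phases.
    """
    phases: list[tuple[float, float, int]] = []
    for a, b in train.intervals:
        mid = (a + b) / 2.0
        phases.append((a, mid, +1))
        phases.append((mid, b, -1))
    return phases


@dataclass
class StimCounters:
    """Delivered-stimulation counters: manual (experimenter) vs animal-triggered."""

    manual: int = 0
    animal: int = 0

    def record_stim(self, source: str) -> "StimCounters":
        if source == "manual":
            self.manual += 1
        elif source == "animal":
            self.animal += 1
        else:
            raise ValueError(f"source must be 'manual' or 'animal', got {source!r}")
        return self

    def clear(self) -> "StimCounters":
        self.manual = 0
        self.animal = 0
        return self
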