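"""The session state machine: zone events, reward sequencing, counters.

The engine consumes a stream of tracking samples and maintains, per active
zone, an occupancy flag evaluated with hysteresis: the zone boundary is the
plain radius for entry and the hysteresis-enlarged radius for exit, and —
following the platform's rule that the radius reverts once the animal leaves
the zone *or the reward is delivered* — the enlargement is dropped for a
rewarded zone as soon as its reward fires.

Reward sequencing follows the one-armed-zone contract: the rewarded-zone list
is an ordered list (repeats allowed); exactly one entry is "armed" at any
time; when the animal satisfies the armed zone's dwell requirement (or the
experimenter presses Next Cue) the next list entry arms.  With
``randomize_rewards`` the next armed id is instead drawn uniformly with
replacement from the list using the session RNG, so runs are reproducible
under ``rng_seed``.

Every zone entry/exit event carries the 8-bit TTL word that the virtual
output bank would present to the acquisition system (see :mod:`mazekit.ttl`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from mazekit.geometry import ZoneSpec, occupancy_test
from mazekit.stim import StimParams
from mazekit.ttl import (
    OutputBank,
    encode_zone_event,
    make_led_event_bank,
    set_led,
)

__all__ = [
    "TrackSample",
    "MazeEvent",
    "SessionConfig",
    "MazeEngine",
    "RejectedSampleError",
    "generate_random_lights_sequence",
]

EVENT_KINDS = (
    "zone_entry",
    "zone_exit",
    "reward",
    "stim_manual",
    "stim_animal",
    "next_cue",
    "led_on",
    "led_off",
    "session_note",
)


class RejectedSampleError(ValueError):
    """Raised for a sample whose timestamp does not advance the stream."""


@dataclass(frozen=True)
class TrackSample:
    """One tracking observation."""

    t: float
    x: float
    y: float
    angle: Optional[float] = None
    valid: bool = True


@dataclass(frozen=True)
class MazeEvent:
    """A timestamped maze event, with its TTL word where one is emitted."""

    t: float
    kind: str
    zone_id: Optional[int] = None
    ttl_word: Optional[str] = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class SessionConfig:
    """Complete experiment definition.

    ``active_zone_ids`` selects which configured zones are tracked this
    session; ``rewarded_zone_ids`` is the ordered arming list (repeats
    allowed) and must be a subset of the active ids.
    """

    zones: list[ZoneSpec]
    active_zone_ids: list[int]
    rewarded_zone_ids: list[int] = field(default_factory=list)
    randomize_rewards: bool = False
    reward_type: str = "liquid"  # none | liquid | stimulation
    stim: Optional[StimParams] = None
    dwell_delay: float = 0.0
    advance_on_passthrough: bool = False
    animal_id: str = ""
    comment: str = ""
    rng_seed: int = 0

    def validate(self) -> None:
        ids = [z.id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zones: duplicate zone ids in session")
        known = set(ids)
        for zid in self.active_zone_ids:
            if zid not in known:
                raise ValueError(f"active_zone_ids: zone {zid} not configured")
        active = set(self.active_zone_ids)
        for zid in self.rewarded_zone_ids:
            if zid not in active:
                raise ValueError(f"rewarded_zone_ids: zone {zid} not in active_zone_ids")
        if self.reward_type not in ("none", "liquid", "stimulation"):
            raise ValueError(f"reward_type: unknown value {self.reward_type!r}")
        if self.dwell_delay < 0:
            raise ValueError(f"dwell_delay: must be >= 0, got {self.dwell_delay}")

    def zone(self, zone_id: int) -> ZoneSpec:
        for z in self.zones:
            if z.id == zone_id:
                return z
        raise KeyError(zone_id)


class MazeEngine:
    """Drives one session: feed samples with :meth:`step`, read ``events``.

    The engine is deterministic: identical config, seed and sample stream
    produce an identical event log.
    """

    def __init__(self, config: SessionConfig, cue_leds: bool = True):
        config.validate()
        self.config = config
        self.cue_leds = cue_leds
        self._zones = {z.id: z for z in config.zones}
        self._inside: dict[int, bool] = {zid: False for zid in config.active_zone_ids}
        self._entry_t: dict[int, float] = {}
        self._rewarded_since_entry: dict[int, bool] = {
            zid: False for zid in config.active_zone_ids
        }
        self._rng = np.random.default_rng(config.rng_seed)
        self._last_t: Optional[float] = None
        self.events: list[MazeEvent] = []
        self.led_bank: OutputBank = make_led_event_bank()
        self.counters_rewards = 0
        self.counters_stim_manual = 0
        self.counters_stim_animal = 0
        self.counters_entries: dict[int, int] = {
            zid: 0 for zid in config.active_zone_ids
        }
        self._armed_idx: Optional[int] = None
        self._armed_id: Optional[int] = None
        self._armed_since: float = 0.0
        if config.rewarded_zone_ids:
            self._armed_idx = 0
            if config.randomize_rewards:
                self._armed_id = self.draw_next_reward()
            else:
                self._armed_id = config.rewarded_zone_ids[0]
            self._set_cue_led(self._armed_id, 0.0)

    # -- public state ------------------------------------------------------

    @property
    def armed_zone_id(self) -> Optional[int]:
        """The single currently armed rewarded zone, if any."""
        return self._armed_id

    def inside(self, zone_id: int) -> bool:
        return self._inside[zone_id]

    def session_counters(self) -> dict:
        """Counter table mirroring the GUI's counters panel."""
        return {
            "rewards": self.counters_rewards,
            "stim_manual": self.counters_stim_manual,
            "stim_animal": self.counters_stim_animal,
            "zone_entries": dict(self.counters_entries),
        }

    # -- randomized arming -------------------------------------------------

    def draw_next_reward(self) -> int:
        """Uniform draw with replacement from the rewarded list (session RNG)."""
        ids = self.config.rewarded_zone_ids
        if not ids:
            raise ValueError("draw_next_reward: rewarded zone list is empty")
        return int(ids[self._rng.integers(0, len(ids))])

    # -- stepping ----------------------------------------------------------

    def step(self, sample: TrackSample) -> list[MazeEvent]:
        """Process one sample; returns the events it produced (also logged)."""
        if self._last_t is not None and sample.t <= self._last_t:
            raise RejectedSampleError(
                f"sample at t={sample.t} does not advance past t={self._last_t}"
            )
        self._last_t = sample.t
        if not sample.valid:
            # tracking dropout: freeze all occupancy state, fabricate nothing
            return []
        produced: list[MazeEvent] = []
        p = (sample.x, sample.y)
        for zid in self.config.active_zone_ids:
            zone = self._zones[zid]
            inside = self._inside[zid]
            # hysteresis is dropped once this occupancy has been rewarded
            use_hyst = inside and not self._rewarded_since_entry[zid]
            occ = occupancy_test(zone, p, use_hyst)
            if occ == inside:
                continue
            self._inside[zid] = occ
            direction = "entry" if occ else "exit"
            word = encode_zone_event(zid, direction).as_string()
            produced.append(
                MazeEvent(
                    t=sample.t,
                    kind="zone_entry" if occ else "zone_exit",
                    zone_id=zid,
                    ttl_word=word,
                )
            )
            if occ:
                self._entry_t[zid] = sample.t
                self.counters_entries[zid] += 1
            else:
                rewarded = self._rewarded_since_entry[zid]
                self._rewarded_since_entry[zid] = False
                if (
                    zid == self._armed_id
                    and not rewarded
                    and self.config.advance_on_passthrough
                ):
                    produced.extend(self._advance_arming(sample.t, "passthrough"))
        produced.extend(self._maybe_reward(sample.t))
        self.events.extend(produced)
        return produced

    def next_cue(self, t: float) -> list[MazeEvent]:
        """Manually advance the armed zone (no reward); logs a next_cue event."""
        if not self.config.rewarded_zone_ids:
            ev = [
                MazeEvent(
                    t=t,
                    kind="session_note",
                    detail="next_cue ignored: no rewarded zones configured",
                )
            ]
            self.events.extend(ev)
            return ev
        produced = [MazeEvent(t=t, kind="next_cue", zone_id=self._armed_id)]
        produced.extend(self._advance_arming(t, "next_cue"))
        self.events.extend(produced)
        return produced

    def record_manual_stim(self, t: float) -> MazeEvent:
        """Experimenter-triggered stimulation (Send Manually)."""
        self.counters_stim_manual += 1
        ev = MazeEvent(t=t, kind="stim_manual")
        self.events.append(ev)
        return ev

    # -- internals ---------------------------------------------------------

    def _dwell_start(self, zid: int) -> float:
        # dwell runs from entry, or from arming if the animal was already in
        return max(self._entry_t.get(zid, self._armed_since), self._armed_since)

    def _maybe_reward(self, t: float) -> list[MazeEvent]:
        zid = self._armed_id
        if zid is None or not self._inside[zid] or self._rewarded_since_entry[zid]:
            return []
        if t - self._dwell_start(zid) < self.config.dwell_delay:
            return []
        self._rewarded_since_entry[zid] = True
        self.counters_rewards += 1
        produced = [MazeEvent(t=t, kind="reward", zone_id=zid)]
        if self.config.reward_type == "stimulation":
            self.counters_stim_animal += 1
            produced.append(MazeEvent(t=t, kind="stim_animal", zone_id=zid))
        produced.extend(self._advance_arming(t, "reward"))
        return produced

    def _advance_arming(self, t: float, why: str) -> list[MazeEvent]:
        prev = self._armed_id
        self._armed_idx = (self._armed_idx + 1) % len(self.config.rewarded_zone_ids)
        if self.config.randomize_rewards:
            self._armed_id = self.draw_next_reward()
        else:
            self._armed_id = self.config.rewarded_zone_ids[self._armed_idx]
        self._armed_since = t
        produced: list[MazeEvent] = []
        if prev != self._armed_id:
            produced.extend(self._unset_cue_led(prev, t))
            produced.extend(self._set_cue_led(self._armed_id, t))
        return produced

    def _set_cue_led(self, zid: Optional[int], t: float) -> list[MazeEvent]:
        return self._drive_cue_led(zid, True, t)

    def _unset_cue_led(self, zid: Optional[int], t: float) -> list[MazeEvent]:
        return self._drive_cue_led(zid, False, t)

    def _drive_cue_led(self, zid: Optional[int], on: bool, t: float) -> list[MazeEvent]:
        if not self.cue_leds or zid is None:
            return []
        led = self._zones[zid].led_index
        if led is None:
            return []
        _, kind = set_led(self.led_bank, led, on, t)
        if kind is None:
            return []
        ev = MazeEvent(t=t, kind=kind, zone_id=zid, detail=f"led={led}")
        if t == 0.0 and not self.events:
            self.events.append(ev)  # initial arming happens before any sample
            return []
        return [ev]


def generate_random_lights_sequence(
    zone_ids: list[int], length: int, seed: int
) -> list[int]:
    """Draw a cue/reward sequence uniformly with replacement from ``zone_ids``."""
    if not zone_ids:
        raise ValueError("zone_ids must be non-empty")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(zone_ids)
    return [int(z) for z in ids[rng.integers(0, len(ids), size=length)]]
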