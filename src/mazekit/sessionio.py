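"""Settings files and log persistence.

Session configurations are stored as schema-versioned canonical JSON so they
diff cleanly and round-trip field-for-field; event and sample logs are UTF-8
CSV with timestamps written as fixed six-decimal seconds for byte-stable
output across platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from mazekit.engine import MazeEvent, SessionConfig, TrackSample
from mazekit.geometry import ZoneSpec
from mazekit.stim import StimParams

__all__ = [
    "SCHEMA_VERSION",
    "SettingsError",
    "save_settings",
    "load_settings",
    "write_event_log",
    "read_event_log",
    "write_sample_log",
    "read_sample_log",
]

SCHEMA_VERSION = "1"

PathLike = Union[str, Path]


class SettingsError(ValueError):
    """A settings file failed validation; the message names the field."""


def save_settings(config: SessionConfig, path: PathLike) -> None:
    """Write a canonical, schema-versioned JSON settings file."""
    config.validate()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "zones": [asdict(z) for z in config.zones],
            "active_zone_ids": list(config.active_zone_ids),
            "rewarded_zone_ids": list(config.rewarded_zone_ids),
            "randomize_rewards": config.randomize_rewards,
            "reward_type": config.reward_type,
            "stim": asdict(config.stim) if config.stim else None,
            "dwell_delay": config.dwell_delay,
            "advance_on_passthrough": config.advance_on_passthrough,
            "animal_id": config.animal_id,
            "comment": config.comment,
            "rng_seed": config.rng_seed,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def load_settings(path: PathLike) -> SessionConfig:
    """Load and validate a settings file; raises SettingsError on any problem."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SettingsError(f"not valid JSON: {e}") from e
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SettingsError(
            f"schema_version: expected {SCHEMA_VERSION!r}, got {version!r}"
        )
    c = doc.get("config")
    if not isinstance(c, dict):
        raise SettingsError("config: missing or not an object")
    try:
        zones = [ZoneSpec(center=tuple(z.pop("center")), **z)
                 for z in [dict(z) for z in c["zones"]]]
        stim = StimParams(**c["stim"]) if c.get("stim") else None
        config = SessionConfig(
            zones=zones,
            active_zone_ids=list(c["active_zone_ids"]),
            rewarded_zone_ids=list(c.get("rewarded_zone_ids", [])),
            randomize_rewards=bool(c.get("randomize_rewards", False)),
            reward_type=c.get("reward_type", "liquid"),
            stim=stim,
            dwell_delay=float(c.get("dwell_delay", 0.0)),
            advance_on_passthrough=bool(c.get("advance_on_passthrough", False)),
            animal_id=c.get("animal_id", ""),
            comment=c.get("comment", ""),
            rng_seed=int(c.get("rng_seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as e:
        raise SettingsError(str(e)) from e
    try:
        config.validate()
    except ValueError as e:
        raise SettingsError(str(e)) from e
    return config


def _fmt_t(t: float) -> str:
    return f"{t:.6f}"


def write_event_log(events: Sequence[MazeEvent], path: PathLike) -> None:
    """Event log CSV: ``t,kind,zone_id,ttl_word,detail``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("t,kind,zone_id,ttl_word,detail\n")
        for ev in events:
            zid = "" if ev.zone_id is None else str(ev.zone_id)
            word = ev.ttl_word or ""
            detail = ev.detail.replace(",", ";")
            fh.write(f"{_fmt_t(ev.t)},{ev.kind},{zid},{word},{detail}\n")


def read_event_log(path: PathLike) -> list[MazeEvent]:
    df = pd.read_csv(path, dtype={"ttl_word": str, "detail": str})
    events = []
    for row in df.itertuples(index=False):
        zid = None if pd.isna(row.zone_id) else int(row.zone_id)
        word = None if pd.isna(row.ttl_word) else str(row.ttl_word)
        detail = "" if pd.isna(row.detail) else str(row.detail)
        events.append(MazeEvent(t=float(row.t), kind=row.kind, zone_id=zid,
                                ttl_word=word, detail=detail))
    return events


def write_sample_log(samples: Sequence[TrackSample], path: PathLike) -> None:
    """Sample log CSV: ``t,x,y,angle,valid``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("t,x,y,angle,valid\n")
        for s in samples:
            angle = "" if s.angle is None else f"{s.angle:.6f}"
            fh.write(
                f"{_fmt_t(s.t)},{s.x:.6f},{s.y:.6f},{angle},{int(s.valid)}\n"
            )


def read_sample_log(path: PathLike) -> list[TrackSample]:
    df = pd.read_csv(path)
    samples = []
    for row in df.itertuples(index=False):
        angle = None if pd.isna(row.angle) else float(row.angle)
        samples.append(
            TrackSample(t=float(row.t), x=float(row.x), y=float(row.y),
                        angle=angle, valid=bool(row.valid))
        )
    return samples
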