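"""Synthetic animal and camera: trajectories, rendered frames, task presets.

The agent model is deliberately simple — piecewise-linear pursuit of a
waypoint list at constant speed, Gaussian positional jitter, optional pauses
at waypoints, and per-sample tracking dropouts.  It exists to exercise the
engine and vision pipeline deterministically, not to model rodent locomotion.

The renderer is the inverse of the tracking pipeline: a dark platform, the
animal as a bright disk (or two colored disks in head-direction mode), and
the perimeter cue LEDs as small bright dots.  Running rendered frames back
through :mod:`mazekit.vision` closes the loop and recovers the commanded
trajectory.

Presets reproduce the configurations of the platform's published tasks:

``spatial_reorientation``
    Linear track, three tracked zones (unreachable start zone advanced via
    Next Cue, a rewarded zone with a dwell delay, an end zone),
    ``advance_on_passthrough`` on, stimulation reward.
``sequence_task``
    Five distinct perimeter zones out of 32; the agent starts at zone 5 and
    the rewarded list is the eight-item loop 1-2-3-4-1-2-3-5; no dwell delay,
    reward on entry.
``random_lights``
    All 32 perimeter zones; the rewarded list is drawn uniformly with
    replacement (up to 900 elements in the published protocol).
``oppa``
    Seven zones (two end platforms, two arms, center, two off-maze zones for
    manual-reward timestamps); reward type none.
``mat_allocentric`` / ``mat_transformation``
    Eight arm zones (starts S1-S7 plus the reward arm R) and a center zone,
    plus an off-maze rewarded-control zone; the rewarded list alternates
    between the reward arm and the off-maze zone so each correct entry
    rewards once until the experimenter re-arms.
``mat_egocentric``
    Same arm/center zones but no rewarded zones: rewards are delivered as
    manually triggered stimulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from mazekit.engine import (
    MazeEngine,
    MazeEvent,
    SessionConfig,
    TrackSample,
    generate_random_lights_sequence,
)
from mazekit.geometry import PerimeterLayout, ZoneSpec, make_perimeter_layout
from mazekit.stim import StimParams

__all__ = [
    "AgentModel",
    "Scene",
    "TaskPreset",
    "PRESET_NAMES",
    "simulate_trajectory",
    "render_frame",
    "render_frames",
    "load_preset",
    "compliant_agent",
    "run_session",
]

# Default synthetic camera geometry: 640x480 frame, platform ring of 32 LEDs.
FRAME_SIZE = (640, 480)
PLATFORM_CENTER = (320.0, 240.0)
RING_RADIUS = 200.0
ZONE_RADIUS = 20.0

PRESET_NAMES = (
    "spatial_reorientation",
    "sequence_task",
    "random_lights",
    "oppa",
    "mat_allocentric",
    "mat_transformation",
    "mat_egocentric",
)


@dataclass(frozen=True)
class AgentModel:
    """Waypoint-pursuit agent with jitter, waypoint dwells and dropouts."""

    waypoints: tuple[tuple[float, float], ...]
    speed: float = 50.0  # px/s
    jitter_sd: float = 0.0  # px
    dwell_at_waypoint: float = 0.0  # s pause on reaching each waypoint
    dropout_prob: float = 0.0  # per-sample P(valid=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.waypoints:
            raise ValueError("waypoints must be non-empty")
        if self.speed <= 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError(f"dropout_prob must be in [0, 1), got {self.dropout_prob}")


@dataclass(frozen=True)
class Scene:
    """What the synthetic camera sees besides the animal."""

    frame_size: tuple[int, int] = FRAME_SIZE
    layout: Optional[PerimeterLayout] = None
    lit_leds: tuple[int, ...] = ()
    background: int = 10
    animal_intensity: int = 220
    animal_radius: float = 6.0
    led_intensity: int = 255
    led_radius: float = 2.0


@dataclass(frozen=True)
class TaskPreset:
    name: str
    config: SessionConfig
    agent: AgentModel
    layout: PerimeterLayout
    notes: str = ""


def _ideal_path(
    waypoints: Sequence[tuple[float, float]], speed: float, dwell: float
):
    """Breakpoints (t, x, y) of the noiseless pursuit path."""
    t = 0.0
    pts = [(t, *waypoints[0])]
    for (x0, y0), (x1, y1) in zip(waypoints, waypoints[1:]):
        if dwell > 0:
            t += dwell
            pts.append((t, x0, y0))
        d = math.hypot(x1 - x0, y1 - y0)
        t += d / speed
        pts.append((t, x1, y1))
    if dwell > 0:
        t += dwell
        pts.append((t, *waypoints[-1]))
    return pts


def simulate_trajectory(
    agent: AgentModel, rate: float, t_max: float
) -> list[TrackSample]:
    """Sample the agent's path at ``rate`` Hz for ``t_max`` seconds.

    The path is piecewise-linear waypoint pursuit at the agent's speed with a
    pause of ``dwell_at_waypoint`` at each waypoint; after the last waypoint
    the agent stays put.  Gaussian jitter and dropouts use the agent's seed,
    so identical agents yield identical streams.  The heading reported with
    each sample is the direction of ideal motion (0 deg when stationary).
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    rng = np.random.default_rng(agent.seed)
    breakpoints = _ideal_path(agent.waypoints, agent.speed, agent.dwell_at_waypoint)
    times = [b[0] for b in breakpoints]
    xs = [b[1] for b in breakpoints]
    ys = [b[2] for b in breakpoints]
    n = int(math.floor(t_max * rate)) + 1
    samples: list[TrackSample] = []
    for i in range(n):
        t = i / rate
        x = float(np.interp(t, times, xs))
        y = float(np.interp(t, times, ys))
        # heading from the ideal (pre-jitter) velocity over one sample period
        t2 = min(t + 1.0 / rate, times[-1])
        dx = float(np.interp(t2, times, xs)) - x
        dy = float(np.interp(t2, times, ys)) - y
        if dx == 0.0 and dy == 0.0:
            angle = 0.0
        else:
            angle = math.degrees(math.atan2(-dy, dx)) % 360.0  # y-up convention
        if agent.jitter_sd > 0:
            x += float(rng.normal(0, agent.jitter_sd))
            y += float(rng.normal(0, agent.jitter_sd))
        valid = bool(rng.random() >= agent.dropout_prob)
        samples.append(TrackSample(t=t, x=x, y=y, angle=angle, valid=valid))
    return samples


def _draw_disk(img: np.ndarray, center: tuple[float, float], radius: float, value: int,
               channel: Optional[int] = None) -> None:
    H, W = img.shape[:2]
    x0, y0 = center
    xmin = max(int(x0 - radius) - 1, 0)
    xmax = min(int(x0 + radius) + 2, W)
    ymin = max(int(y0 - radius) - 1, 0)
    ymax = min(int(y0 + radius) + 2, H)
    yy, xx = np.mgrid[ymin:ymax, xmin:xmax]
    mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= radius**2
    if channel is None:
        img[ymin:ymax, xmin:xmax][mask] = value
    else:
        img[ymin:ymax, xmin:xmax, channel][mask] = value


def render_frame(
    sample: Optional[TrackSample],
    scene: Scene,
    head_direction_mode: bool = False,
    marker_spacing: float = 8.0,
) -> np.ndarray:
    """Render one synthetic camera frame.

    Single-marker mode draws one bright grayscale disk at the sample
    position; head-direction mode returns a 3-channel frame with the front
    marker in channel 0 and the rear marker in channel 1, separated by
    ``marker_spacing`` along the sample's heading.  Lit LEDs are drawn as
    small dots at their layout positions (the layout's y-up offsets are
    flipped into the pixel frame).  Invalid or absent samples render without
    the animal.
    """
    W, H = scene.frame_size
    shape = (H, W, 3) if head_direction_mode else (H, W)
    img = np.full(shape, scene.background, dtype=np.uint8)
    if scene.layout is not None:
        for led in scene.lit_leds:
            lx, ly = _layout_pixel(scene.layout, led)
            _draw_disk(img, (lx, ly), scene.led_radius, scene.led_intensity)
    if sample is not None and sample.valid:
        if head_direction_mode:
            a = math.radians(sample.angle or 0.0)
            hx, hy = math.cos(a), -math.sin(a)  # y-up angle -> pixel frame
            fx = sample.x + hx * marker_spacing / 2
            fy = sample.y + hy * marker_spacing / 2
            rx = sample.x - hx * marker_spacing / 2
            ry = sample.y - hy * marker_spacing / 2
            _draw_disk(img, (fx, fy), scene.animal_radius / 2, scene.animal_intensity, 0)
            _draw_disk(img, (rx, ry), scene.animal_radius / 2, scene.animal_intensity, 1)
        else:
            _draw_disk(img, (sample.x, sample.y), scene.animal_radius,
                       scene.animal_intensity)
    return img


def render_frames(
    samples: Sequence[TrackSample], scene: Scene, head_direction_mode: bool = False
):
    """Yield one frame per sample (generator, frames can be large)."""
    for s in samples:
        yield render_frame(s, scene, head_direction_mode)


def _layout_pixel(layout: PerimeterLayout, index: int) -> tuple[float, float]:
    """Layout position in pixel coordinates (y-up offset flipped to y-down)."""
    x, y = layout.position(index)
    cx, cy = layout.center
    return (x, cy - (y - cy))


def _perimeter_zone(layout: PerimeterLayout, zone_id: int, led_index: int,
                    radius: float = ZONE_RADIUS) -> ZoneSpec:
    return ZoneSpec(
        id=zone_id,
        center=_layout_pixel(layout, led_index),
        radius=radius,
        led_index=led_index,
    )


def load_preset(name: str, seed: int = 0, random_lights_length: int = 900) -> TaskPreset:
    """Build the ready-made configuration + agent for one of the task presets."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    layout = make_perimeter_layout(32, PLATFORM_CENTER, RING_RADIUS, start_angle=90.0)

    if name == "sequence_task":
        # five distinct perimeter zones; the configured eight-item loop
        led_for_zone = {1: 1, 2: 8, 3: 14, 4: 20, 5: 27}
        zones = [_perimeter_zone(layout, z, led) for z, led in led_for_zone.items()]
        rewarded = [1, 2, 3, 4, 1, 2, 3, 5]
        config = SessionConfig(
            zones=zones,
            active_zone_ids=[1, 2, 3, 4, 5],
            rewarded_zone_ids=rewarded,
            reward_type="stimulation",
            stim=StimParams(frequency=100.0, duration=0.5, duty_cycle=50.0),
            dwell_delay=0.0,
            rng_seed=seed,
        )
        start = config.zone(5).center
        agent = AgentModel(
            waypoints=(start,) + tuple(config.zone(z).center for z in rewarded),
            speed=120.0,
            seed=seed,
        )
        return TaskPreset(name, config, agent, layout,
                          notes="starts at zone 5; loop 1-2-3-4-1-2-3-5")

    if name == "random_lights":
        zones = [_perimeter_zone(layout, k, k) for k in range(1, 33)]
        rewarded = generate_random_lights_sequence(list(range(1, 33)),
                                                   random_lights_length, seed)
        config = SessionConfig(
            zones=zones,
            active_zone_ids=list(range(1, 33)),
            rewarded_zone_ids=rewarded,
            reward_type="liquid",
            dwell_delay=0.0,
            rng_seed=seed,
        )
        agent = AgentModel(
            waypoints=tuple(config.zone(z).center for z in rewarded[:50]) or
            (PLATFORM_CENTER,),
            speed=150.0,
            seed=seed,
        )
        return TaskPreset(name, config, agent, layout,
                          notes=f"{random_lights_length}-element drawn sequence")

    if name == "spatial_reorientation":
        # linear track across the platform; the start zone is virtual
        # (unreachable) and trials are advanced with Next Cue
        track_y = 240.0
        zones = [
            ZoneSpec(id=1, center=(-100.0, track_y), radius=ZONE_RADIUS),  # start
            ZoneSpec(id=2, center=(320.0, track_y), radius=ZONE_RADIUS),  # rewarded
            ZoneSpec(id=3, center=(520.0, track_y), radius=ZONE_RADIUS),  # end
        ]
        config = SessionConfig(
            zones=zones,
            active_zone_ids=[1, 2, 3],
            rewarded_zone_ids=[2],
            reward_type="stimulation",
            stim=StimParams(frequency=100.0, duration=0.5, duty_cycle=50.0),
            dwell_delay=1.5,
            advance_on_passthrough=True,
            rng_seed=seed,
        )
        agent = AgentModel(
            waypoints=((120.0, track_y), (320.0, track_y), (520.0, track_y)),
            speed=100.0,
            dwell_at_waypoint=2.0,
            seed=seed,
        )
        return TaskPreset(name, config, agent, layout,
                          notes="3 zones: virtual start / rewarded+delay / end")

    if name == "oppa":
        # plus-shaped two-arm maze: end platforms, arms, center, two off-maze
        cx, cy = PLATFORM_CENTER
        zones = [
            ZoneSpec(id=1, center=(cx - 180, cy), radius=ZONE_RADIUS),  # west platform
            ZoneSpec(id=2, center=(cx + 180, cy), radius=ZONE_RADIUS),  # east platform
            ZoneSpec(id=3, center=(cx - 90, cy), radius=ZONE_RADIUS),  # west arm
            ZoneSpec(id=4, center=(cx + 90, cy), radius=ZONE_RADIUS),  # east arm
            ZoneSpec(id=5, center=(cx, cy), radius=ZONE_RADIUS),  # center
            ZoneSpec(id=6, center=(cx - 300, cy - 220), radius=ZONE_RADIUS),  # off-maze
            ZoneSpec(id=7, center=(cx + 300, cy - 220), radius=ZONE_RADIUS),  # off-maze
        ]
        config = SessionConfig(
            zones=zones,
            active_zone_ids=[1, 2, 3, 4, 5, 6, 7],
            rewarded_zone_ids=[],
            reward_type="none",
            rng_seed=seed,
        )
        agent = AgentModel(
            waypoints=(zones[4].center, zones[2].center, zones[0].center,
                       zones[2].center, zones[4].center, zones[3].center,
                       zones[1].center),
            speed=100.0,
            seed=seed,
        )
        return TaskPreset(name, config, agent, layout,
                          notes="7 zones, manual food reward (reward type none)")

    # MAT family: 8 arm zones (S1-S7 + R) + center + off-maze control zone
    cx, cy = PLATFORM_CENTER
    arm_r = 180.0
    zones = []
    for k in range(8):  # arm ends, every 45 deg; zone 8 is the reward arm R
        a = math.radians(90.0 + k * 45.0)
        zones.append(
            ZoneSpec(id=k + 1, center=(cx + arm_r * math.cos(a),
                                       cy - arm_r * math.sin(a)),
                     radius=ZONE_RADIUS)
        )
    zones.append(ZoneSpec(id=9, center=(cx, cy), radius=ZONE_RADIUS))  # center
    zones.append(ZoneSpec(id=10, center=(cx + 300, cy - 220), radius=ZONE_RADIUS))
    reward_arm = 8
    off_maze = 10
    if name == "mat_egocentric":
        config = SessionConfig(
            zones=zones,
            active_zone_ids=list(range(1, 11)),
            rewarded_zone_ids=[],
            reward_type="none",
            stim=StimParams(frequency=100.0, duration=0.5, duty_cycle=50.0),
            rng_seed=seed,
        )
        notes = "rewards delivered as manual stimulations"
    else:
        config = SessionConfig(
            zones=zones,
            active_zone_ids=list(range(1, 11)),
            rewarded_zone_ids=[reward_arm, off_maze],
            reward_type="stimulation",
            stim=StimParams(frequency=100.0, duration=0.5, duty_cycle=50.0),
            dwell_delay=0.0,
            rng_seed=seed,
        )
        notes = "one armed zone; off-maze zone closes trials and gates re-arming"
    agent = AgentModel(
        waypoints=(zones[0].center, zones[8].center, zones[reward_arm - 1].center),
        speed=100.0,
        seed=seed,
    )
    return TaskPreset(name, config, agent, layout, notes=notes)


def compliant_agent(config: SessionConfig, speed: float = 120.0,
                    dwell: Optional[float] = None, seed: int = 0,
                    start: Optional[tuple[float, float]] = None) -> AgentModel:
    """An agent that visits the rewarded zones in list order, honoring dwell."""
    if dwell is None:
        dwell = config.dwell_delay + 0.2 if config.dwell_delay > 0 else 0.0
    centers: list[tuple[float, float]] = [] if start is None else [start]
    for z in config.rewarded_zone_ids:
        c = config.zone(z).center
        if centers and centers[-1] == c:
            # repeated zone: detour via the platform center so the agent
            # exits and re-enters, re-triggering the reward
            centers.append(PLATFORM_CENTER)
        centers.append(c)
    return AgentModel(waypoints=tuple(centers), speed=speed,
                      dwell_at_waypoint=dwell, seed=seed)


def run_session(
    preset: TaskPreset, t_max: float, seed: int = 0, rate: float = 30.0
) -> tuple[list[MazeEvent], list[TrackSample]]:
    """Drive the preset's agent through the engine; returns (events, samples)."""
    agent = preset.agent if preset.agent.seed == seed else \
        AgentModel(**{**preset.agent.__dict__, "seed": seed})
    config = preset.config
    if config.rng_seed != seed:
        config = SessionConfig(**{**config.__dict__, "rng_seed": seed})
    samples = simulate_trajectory(agent, rate, t_max)
    engine = MazeEngine(config)
    for s in samples:
        engine.step(s)
    return engine.events, samples
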