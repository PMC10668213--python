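"""Circular-zone geometry and the platform's evenly spaced perimeter layout.

Coordinates are camera-pixel coordinates: origin at the top-left of the frame,
x rightward, y downward.  Angles, however, follow the mathematical convention:
degrees in [0, 360), 0 deg along +x, increasing counterclockwise in a y-up
frame.  A renderer working in pixel coordinates must therefore flip the sign
of the y offset (see :mod:`mazekit.simulate`); the layout functions here
return y-up offsets added to the pixel-frame center, which makes angle 90 deg
appear *above* the center only after that flip.  All geometric predicates are
frame-agnostic since they only use distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ZoneSpec",
    "PerimeterLayout",
    "make_perimeter_layout",
    "occupancy_test",
    "led_to_spout_map",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class ZoneSpec:
    """A circular spatial zone of interest.

    Parameters
    ----------
    id : int
        Zone number, 1-32, unique within a session.
    center : (float, float)
        Zone center in pixels.
    radius : float
        Zone radius in pixels, > 0.
    hysteresis_factor : float
        Multiplier (>= 1) applied to the radius while the animal is inside,
        suppressing false exits from small head movements.
    led_index : int, optional
        Perimeter LED (1-32) associated with the zone, used as a cue light.
    role : {"tracked", "rewarded"}
        Whether the zone only timestamps entries/exits or can also arm for
        reward delivery.
    """

    id: int
    center: Point
    radius: float
    hysteresis_factor: float = 1.5
    led_index: Optional[int] = None
    role: str = "tracked"

    def __post_init__(self) -> None:
        if not (1 <= self.id <= 32):
            raise ValueError(f"zone id must be 1-32, got {self.id}")
        if self.radius <= 0:
            raise ValueError(f"zone radius must be > 0, got {self.radius}")
        if self.hysteresis_factor < 1:
            raise ValueError(
                f"hysteresis_factor must be >= 1, got {self.hysteresis_factor}"
            )
        if self.led_index is not None and not (1 <= self.led_index <= 32):
            raise ValueError(f"led_index must be 1-32, got {self.led_index}")
        if self.role not in ("tracked", "rewarded"):
            raise ValueError(f"role must be 'tracked' or 'rewarded', got {self.role!r}")

    def effective_radius(self, currently_inside: bool) -> float:
        """Radius in force given the occupancy state (hysteresis-enlarged inside)."""
        return self.radius * self.hysteresis_factor if currently_inside else self.radius


@dataclass(frozen=True)
class PerimeterLayout:
    """Evenly spaced positions on a ring, e.g. the 32 wall LEDs of the platform."""

    n_positions: int
    center: Point
    ring_radius: float
    positions: tuple[Point, ...] = field(default=())

    def position(self, index: int) -> Point:
        """1-based lookup of position ``index``."""
        if not (1 <= index <= self.n_positions):
            raise IndexError(f"position index must be 1-{self.n_positions}")
        return self.positions[index - 1]


def make_perimeter_layout(
    n: int, center: Point, ring_radius: float, start_angle: float = 0.0
) -> PerimeterLayout:
    """Place ``n`` evenly spaced positions on a ring.

    Position ``k`` (1-based) sits at angle ``start_angle + (k-1) * 360/n``
    degrees, at distance ``ring_radius`` from ``center``, in the y-up angle
    convention described in the module docstring.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if ring_radius <= 0:
        raise ValueError(f"ring_radius must be > 0, got {ring_radius}")
    cx, cy = center
    step = 360.0 / n
    positions = []
    for k in range(n):
        a = math.radians(start_angle + k * step)
        positions.append((cx + ring_radius * math.cos(a), cy + ring_radius * math.sin(a)))
    return PerimeterLayout(
        n_positions=n, center=center, ring_radius=ring_radius, positions=tuple(positions)
    )


def occupancy_test(zone: ZoneSpec, p: Point, currently_inside: bool) -> bool:
    """True iff ``p`` lies within the zone's effective radius.

    The effective radius is the plain radius when the animal is outside and
    ``radius * hysteresis_factor`` while it is inside, so a point must retreat
    past the enlarged boundary to register an exit.  A distance exactly equal
    to the effective radius counts as inside (closed disk).
    """
    dx = p[0] - zone.center[0]
    dy = p[1] - zone.center[1]
    return math.hypot(dx, dy) <= zone.effective_radius(currently_inside)


def led_to_spout_map(layout: PerimeterLayout, leds_per_spout: int) -> dict[int, int]:
    """Map each perimeter LED to its nearest reward spout.

    Spouts sit over every ``leds_per_spout``-th LED starting at LED 1, i.e. at
    LED indices 1, 1 + leds_per_spout, ...  Each LED maps to the angularly
    nearest spout (wrapping around the ring); exact ties go to the
    lower-indexed spout.

    Returns
    -------
    dict
        LED index (1-based) -> spout number (1-based, in placement order).
    """
    n = layout.n_positions
    if leds_per_spout < 1 or n % leds_per_spout != 0:
        raise ValueError(
            f"leds_per_spout ({leds_per_spout}) must divide n_positions ({n})"
        )
    spout_leds = list(range(1, n + 1, leds_per_spout))
    mapping: dict[int, int] = {}
    for led in range(1, n + 1):
        best_spout = None
        best_dist = None
        for s, sled in enumerate(spout_leds, start=1):
            d = abs(led - sled) % n
            d = min(d, n - d)  # wraparound angular distance in LED steps
            if best_dist is None or d < best_dist:
                best_dist, best_spout = d, s
        mapping[led] = best_spout
    return mapping
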