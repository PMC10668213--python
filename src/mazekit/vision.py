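"""Blob-tracking video pipeline and sequential-LED auto-calibration.

The pipeline mirrors a standard real-time tracking workflow: grayscale
threshold -> 8-connected binary regions -> largest region -> plain (unweighted)
binary centroid -> normalization by frame size.  Head direction comes from two
colored markers: the angle of the rear->front vector in the package angle
convention (0 deg along +x, counterclockwise-positive in a y-up frame; pixel y
points down, so the y offset is negated).  When either marker is missing the
heading is reported as 0 deg with a single-marker flag, matching the tracker's
displayed fallback.

Positions are streamed as OSC 1.0 binary messages to address ``/position``
with typetags ``,ifffi`` and payload
``[frame_index, x_norm, y_norm, angle_deg, valid]`` — a fixed, versioned
schema so any consumer can decode the stream bit-exactly.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "RegionStats",
    "HeadDirection",
    "CalibrationError",
    "threshold_frame",
    "find_regions",
    "largest_region",
    "normalize_position",
    "denormalize_position",
    "head_direction",
    "track_frame",
    "autocalibrate",
    "PositionMessage",
    "serialize_message",
    "parse_message",
]

MIN_REGION_AREA = 5  # px; floor rejecting single-pixel noise
OSC_ADDRESS = "/position"
OSC_TYPETAGS = ",ifffi"


@dataclass(frozen=True)
class RegionStats:
    """Area and plain binary centroid of one connected component."""

    area: int
    centroid: tuple[float, float]  # (x, y) pixels


@dataclass(frozen=True)
class HeadDirection:
    angle_deg: float
    single_marker: bool = False


class CalibrationError(RuntimeError):
    """Auto-calibration failed for a specific LED index."""

    def __init__(self, led_index: int, message: str):
        self.led_index = led_index
        super().__init__(f"LED {led_index}: {message}")


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel frame to grayscale (channel mean); pass gray through."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        return frame.mean(axis=2)
    return frame


def threshold_frame(frame: np.ndarray, T: float) -> np.ndarray:
    """Binary mask: pixel >= T -> 1 else 0 (color frames converted first)."""
    gray = to_grayscale(frame)
    return (gray >= T).astype(np.uint8)


def find_regions(binary: np.ndarray) -> list[RegionStats]:
    """Stats of every 8-connected component of a binary frame.

    Centroids are unweighted pixel-coordinate means, returned as (x, y);
    a blank frame yields an empty list.
    """
    binary = np.asarray(binary)
    labels = measure.label(binary > 0, connectivity=2)
    out = []
    for rp in measure.regionprops(labels):
        cy, cx = rp.centroid  # regionprops is (row, col)
        out.append(RegionStats(area=int(rp.area), centroid=(float(cx), float(cy))))
    return out


def largest_region(
    regions: Sequence[RegionStats], min_area: int = MIN_REGION_AREA
) -> Optional[RegionStats]:
    """Largest region by area after the noise floor; deterministic tie-break.

    Ties resolve to the smallest (y, then x) centroid.  Returns None when no
    region survives the floor (the sample is then flagged invalid).
    """
    candidates = [r for r in regions if r.area >= min_area]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (-r.area, r.centroid[1], r.centroid[0]))


def normalize_position(
    p: tuple[float, float], frame_size: tuple[int, int]
) -> tuple[float, float]:
    """(x, y) pixels -> (x/W, y/H) in [0, 1], clamping out-of-frame points."""
    W, H = frame_size
    x = min(max(p[0], 0.0), float(W))
    y = min(max(p[1], 0.0), float(H))
    return (x / W, y / H)


def denormalize_position(
    p_norm: tuple[float, float], frame_size: tuple[int, int]
) -> tuple[float, float]:
    W, H = frame_size
    return (p_norm[0] * W, p_norm[1] * H)


def head_direction(
    front: Optional[tuple[float, float]], rear: Optional[tuple[float, float]]
) -> HeadDirection:
    """Heading of the rear->front marker vector, in degrees [0, 360).

    Marker points are pixel coordinates (y down); the returned angle is in the
    y-up convention, so a front marker directly above the rear one is 90 deg.
    Missing or coincident markers fall back to 0 deg with ``single_marker``
    set, mirroring the tracker's displayed behavior.
    """
    if front is None or rear is None:
        return HeadDirection(angle_deg=0.0, single_marker=True)
    dx = front[0] - rear[0]
    dy = -(front[1] - rear[1])  # pixel y is down; angles are y-up
    if dx == 0.0 and dy == 0.0:
        return HeadDirection(angle_deg=0.0, single_marker=True)
    return HeadDirection(angle_deg=math.degrees(math.atan2(dy, dx)) % 360.0)


def track_frame(
    frame: np.ndarray, T: float, min_area: int = MIN_REGION_AREA
) -> tuple[Optional[tuple[float, float]], bool]:
    """Full single-marker pipeline on one frame.

    Returns ``(centroid_xy, valid)``: the largest-bright-region centroid, or
    ``(None, False)`` when nothing exceeds the threshold and area floor.
    """
    region = largest_region(find_regions(threshold_frame(frame, T)), min_area)
    if region is None:
        return None, False
    return region.centroid, True


def autocalibrate(
    controller: Callable[[int, bool], None],
    camera: Callable[[], np.ndarray],
    n_leds: int,
    T: float,
    frames_per_led: int = 3,
    min_area: int = 2,
) -> list[tuple[float, float]]:
    """Locate maze zones by flashing the wall LEDs one at a time.

    For each LED k = 1..n_leds: light it via ``controller(k, True)``, grab
    ``frames_per_led`` frames, take their pixelwise median (to reject a
    transient glitch frame), threshold, and record the detected spot's
    centroid as zone k's center; then switch the LED off.  A lit LED is a
    small spot, so the area floor is lower than the animal-tracking one.

    Raises
    ------
    CalibrationError
        Naming LED k, when no spot (occluded/dead LED) or more than one spot
        above the floor (ambient light, reflection) is found.
    """
    centers: list[tuple[float, float]] = []
    for k in range(1, n_leds + 1):
        controller(k, True)
        frames = np.stack([np.asarray(camera(), dtype=float) for _ in range(frames_per_led)])
        controller(k, False)
        frame = np.median(frames, axis=0)
        regions = [r for r in find_regions(threshold_frame(frame, T)) if r.area >= min_area]
        if not regions:
            raise CalibrationError(k, "no bright region detected")
        if len(regions) > 1:
            raise CalibrationError(
                k, f"ambiguous: {len(regions)} regions above the area floor"
            )
        centers.append(regions[0].centroid)
    return centers


# -- streaming position messages (OSC 1.0 binary framing) -------------------


@dataclass(frozen=True)
class PositionMessage:
    """The fixed streaming schema: one tracked position per message."""

    frame_index: int
    x_norm: float
    y_norm: float
    angle_deg: float
    valid: bool


def _osc_pad(b: bytes) -> bytes:
    return b + b"\x00" * (4 - len(b) % 4)  # OSC strings are NUL-padded to 4


def serialize_message(msg: PositionMessage) -> bytes:
    """Encode as an OSC message: address /position, typetags ,ifffi."""
    out = _osc_pad(OSC_ADDRESS.encode())
    out += _osc_pad(OSC_TYPETAGS.encode())
    out += struct.pack(
        ">ifffi",
        msg.frame_index,
        msg.x_norm,
        msg.y_norm,
        msg.angle_deg,
        1 if msg.valid else 0,
    )
    return out


def parse_message(data: bytes) -> PositionMessage:
    """Decode an OSC /position message; rejects other addresses or typetags."""

    def read_padded(buf: bytes, off: int) -> tuple[str, int]:
        end = buf.index(b"\x00", off)
        s = buf[off:end].decode()
        off = end + (4 - end % 4)
        return s, off

    addr, off = read_padded(data, 0)
    if addr != OSC_ADDRESS:
        raise ValueError(f"unexpected OSC address {addr!r}")
    tags, off = read_padded(data, off)
    if tags != OSC_TYPETAGS:
        raise ValueError(f"unexpected OSC typetags {tags!r}")
    frame_index, x, y, angle, valid = struct.unpack_from(">ifffi", data, off)
    return PositionMessage(
        frame_index=frame_index,
        x_norm=x,
        y_norm=y,
        angle_deg=angle,
        valid=bool(valid),
    )
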