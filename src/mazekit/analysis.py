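"""Post-session analyses: trials, velocity profiles, exclusions, criteria.

These mirror the platform's offline workflow for linear-track sessions: the
event log is cut into trials (trial start to end-zone arrival), each trial's
speed is computed from the tracking samples and expressed as a function of
the animal's signed position relative to the reward zone, trials with long
tracking gaps are excluded, and session-level percent-correct series are
tested against a k-of-n performance criterion.

Signed position is the 1-D projection onto the track axis (the start->end
direction), with the reward-zone center at 0 — negative values are before
the zone on the outbound run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from mazekit.engine import MazeEvent, TrackSample

__all__ = [
    "Trial",
    "VelocityProfile",
    "segment_trials",
    "velocity_profile",
    "exclude_lost_tracking",
    "interpolate_gaps",
    "criterion_met",
]

DEFAULT_BIN_WIDTH = 5.0  # px
DEFAULT_SMOOTH_WINDOW = 5  # samples
DEFAULT_MAX_GAP = 0.5  # s


@dataclass
class Trial:
    """One start->end traversal with its samples and optional reward time."""

    start_t: float
    end_t: float
    samples: list[TrackSample]
    reward_t: Optional[float] = None
    start_offset: float = 0.0  # px distance of trial start from the reward zone

    def __post_init__(self) -> None:
        if self.start_t >= self.end_t:
            raise ValueError("trial start_t must precede end_t")


@dataclass
class VelocityProfile:
    """Mean speed per signed-distance bin relative to the reward-zone center."""

    bin_edges: np.ndarray  # length n_bins + 1, px
    mean_speed: np.ndarray  # length n_bins, px/s (NaN for empty bins)
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def segment_trials(
    events: Sequence[MazeEvent],
    samples: Sequence[TrackSample],
    end_zone_id: int,
    start_zone_id: Optional[int] = None,
    reward_zone_id: Optional[int] = None,
) -> tuple[list[Trial], list[str]]:
    """Cut an event log into trials.

    A trial starts at an entry into ``start_zone_id`` — or, when the start
    zone is virtual/unreachable (``start_zone_id=None``), at each ``next_cue``
    press — and ends at the following entry into ``end_zone_id``.  The first
    reward event inside the window is attached as ``reward_t``.  Unpaired
    starts (no end before the next start or the log's end) are dropped and
    reported in the warning list.
    """
    starts: list[float] = []
    for ev in events:
        if start_zone_id is None:
            if ev.kind == "next_cue":
                starts.append(ev.t)
        elif ev.kind == "zone_entry" and ev.zone_id == start_zone_id:
            starts.append(ev.t)
    ends = [ev.t for ev in events
            if ev.kind == "zone_entry" and ev.zone_id == end_zone_id]
    rewards = [ev.t for ev in events if ev.kind == "reward"]

    trials: list[Trial] = []
    warnings: list[str] = []
    for i, t0 in enumerate(starts):
        t_limit = starts[i + 1] if i + 1 < len(starts) else math.inf
        t1 = next((te for te in ends if t0 < te <= t_limit), None)
        if t1 is None:
            warnings.append(f"trial starting at t={t0:.3f}s has no end-zone entry")
            continue
        rt = next((tr for tr in rewards if t0 <= tr <= t1), None)
        tr_samples = [s for s in samples if t0 <= s.t <= t1]
        trials.append(Trial(start_t=t0, end_t=t1, samples=tr_samples, reward_t=rt))
    return trials, warnings


def _signed_distance(
    samples: Sequence[TrackSample], reward_center: tuple[float, float],
    track_axis: Optional[tuple[float, float]],
) -> np.ndarray:
    xy = np.array([[s.x, s.y] for s in samples], dtype=float)
    rel = xy - np.asarray(reward_center, dtype=float)
    if track_axis is None:
        # infer the axis from overall motion: first -> last sample
        v = xy[-1] - xy[0]
        if np.allclose(v, 0):
            v = np.array([1.0, 0.0])
        track_axis = v
    u = np.asarray(track_axis, dtype=float)
    u = u / np.linalg.norm(u)
    return rel @ u


def velocity_profile(
    trial: Trial,
    reward_center: tuple[float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    track_axis: Optional[tuple[float, float]] = None,
) -> VelocityProfile:
    """Speed vs. signed track position relative to the reward zone.

    Speed is a central finite difference over the trial's valid samples,
    optionally smoothed with a centered moving average, then averaged within
    ``bin_width`` bins of the signed along-track distance.  Trials with fewer
    than two valid samples yield an empty, excluded profile.
    """
    valid = [s for s in trial.samples if s.valid]
    if len(valid) < 2:
        return VelocityProfile(
            bin_edges=np.array([0.0, bin_width]),
            mean_speed=np.array([np.nan]),
            excluded=True,
            exclusion_reason="fewer than 2 valid samples",
        )
    xy = np.array([[s.x, s.y] for s in valid])
    t = np.array([s.t for s in valid])
    speed = np.empty(len(valid))
    speed[1:-1] = np.linalg.norm(xy[2:] - xy[:-2], axis=1) / (t[2:] - t[:-2])
    speed[0] = np.linalg.norm(xy[1] - xy[0]) / (t[1] - t[0])
    speed[-1] = np.linalg.norm(xy[-1] - xy[-2]) / (t[-1] - t[-2])
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, kernel, mode="valid")[: len(valid)]
    d = _signed_distance(valid, reward_center, track_axis)
    lo = math.floor(d.min() / bin_width) * bin_width
    hi = math.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    mean_speed = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            mean_speed[b] = speed[m].mean()
    return VelocityProfile(bin_edges=edges, mean_speed=mean_speed)


def exclude_lost_tracking(
    trial: Trial, max_gap: float = DEFAULT_MAX_GAP
) -> tuple[bool, str]:
    """Flag a trial whose longest run of invalid samples exceeds ``max_gap``.

    The gap length is the time spanned from the last valid sample before the
    run to the first valid sample after it (an unterminated trailing run
    extends to the trial end).
    """
    last_valid_t: Optional[float] = trial.start_t
    gap_open: Optional[float] = None
    worst = 0.0
    for s in trial.samples:
        if s.valid:
            if gap_open is not None:
                worst = max(worst, s.t - gap_open)
                gap_open = None
            last_valid_t = s.t
        elif gap_open is None:
            gap_open = last_valid_t if last_valid_t is not None else s.t
    if gap_open is not None:
        worst = max(worst, trial.end_t - gap_open)
    if worst > max_gap:
        return True, f"lost tracking for {worst:.3f}s (max allowed {max_gap:g}s)"
    return False, ""


def interpolate_gaps(trial: Trial) -> Trial:
    """Fill invalid samples by linear interpolation between valid neighbors.

    Intended for trials that survive :func:`exclude_lost_tracking`; leading or
    trailing invalid runs are held at the nearest valid fix.
    """
    t = np.array([s.t for s in trial.samples])
    valid = np.array([s.valid for s in trial.samples])
    if not valid.any():
        return trial
    xv = np.array([s.x for s in trial.samples])[valid]
    yv = np.array([s.y for s in trial.samples])[valid]
    tv = t[valid]
    filled = []
    for i, s in enumerate(trial.samples):
        if s.valid:
            filled.append(s)
        else:
            filled.append(
                TrackSample(
                    t=s.t,
                    x=float(np.interp(s.t, tv, xv)),
                    y=float(np.interp(s.t, tv, yv)),
                    angle=s.angle,
                    valid=True,
                )
            )
    return Trial(
        start_t=trial.start_t,
        end_t=trial.end_t,
        samples=filled,
        reward_t=trial.reward_t,
        start_offset=trial.start_offset,
    )


def criterion_met(
    session_pct_correct: Sequence[float],
    threshold: float = 80.0,
    k_of_n: tuple[int, int] = (3, 4),
    any_window: bool = False,
) -> bool:
    """k-of-n performance criterion on a percent-correct session series.

    True iff, within the most recent ``n`` sessions (or, with ``any_window``,
    within any ``n`` consecutive sessions), at least ``k`` have percent
    correct *strictly* greater than ``threshold``.  Fewer than ``n`` sessions
    is insufficient data and raises.
    """
    k, n = k_of_n
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    pcts = list(session_pct_correct)
    if len(pcts) < n:
        raise ValueError(
            f"insufficient data: {len(pcts)} sessions, criterion needs {n}"
        )
    windows = (
        [pcts[i : i + n] for i in range(len(pcts) - n + 1)]
        if any_window
        else [pcts[-n:]]
    )
    return any(sum(p > threshold for p in w) >= k for w in windows)
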