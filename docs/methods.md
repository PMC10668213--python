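# Methods

## The control model

A session is defined by a set of circular zones (center, radius, hysteresis
factor, optional cue-LED index), an *active* subset that is tracked, and an
ordered *rewarded* list drawn from the active subset, in which repeats are
allowed. The engine consumes a stream of `(t, x, y, angle, valid)` tracking
samples with strictly increasing timestamps and maintains one occupancy flag
per active zone.

**Occupancy and hysteresis.** Entry is tested against the plain radius, exit
against `radius x hysteresis_factor` (default 1.5; the factor is a per-zone
parameter because the original description only says the radius is
temporarily increased, not by how much). A distance exactly equal to the
effective radius counts as inside — the closed disk is the simplest
convention to state and test. The enlargement is dropped as soon as the
zone's reward has fired for the current occupancy, mirroring the rule that
the radius reverts when the animal leaves *or the reward is delivered*.
Overlapping zones are evaluated independently; each gets its own entry/exit
timestamps.

**Arming and dwell.** Exactly one element of the rewarded list is armed at
any time. The dwell timer runs from the entry sample into the armed zone (or
from the arming instant, if the animal was already inside when the zone
armed); leaving the zone — judged by the hysteresis radius — resets it, and
the zone stays armed after a failed dwell. When continuous occupancy reaches
`dwell_delay` the reward fires, at most once per occupancy, and the next
list element arms (wrapping at the end). `advance_on_passthrough`
(default off) additionally advances the arming when the animal exits the
armed zone without earning the reward — the behavior the linear-track
reorientation task needs. With `randomize_rewards` the next armed id is a
uniform draw *with replacement* from the list using the session RNG
(`numpy.random.default_rng(rng_seed)`); with-replacement is the sampling
scheme of the random-lights protocol, and a without-replacement shuffle was
deliberately not made the default. `next_cue` advances the arming manually
without a reward.

**Invalid samples** (tracking dropouts) freeze all occupancy state: no
entries, exits or rewards can be produced by a dropout, so lost tracking
never fabricates events. All timing is in seconds from sample timestamps;
nothing depends on the frame rate.

**TTL layout.** Zone events leave the engine as an 8-bit word: lines 0–5
carry the zone number big-endian (line 0 = MSB), line 6 is the direction
flag (entry = 1), line 7 a one-tick strobe. The original description fixes
only that the zone number goes out "in binary"; the bit order, the strobe
and the explicit entry/exit flag are this package's documented choices so
that decoding is unambiguous, and `decode_zone_event` is the exact inverse.
Valve openings are modeled as a rise/fall pair on the 16-line valve bank
(default open time 0.1 s, configurable — the physical reward volume is not a
software quantity).

## Stimulation

A train with frequency `f`, duration `D` and duty cycle `d` contains
`n = floor(f D)` complete cycles of length `1/f`, each high for `d/100` of
its length from cycle onset; a partial trailing cycle is dropped, so the
total high time is exactly `n (d/100) / f`. At `d = 100` the cycles coalesce
into one contiguous high span. Edge triggering scans a sampled 0/1 input
line for the selected transition and ignores edges arriving within one train
duration of the previous onset (lockout). The bipolar conversion performed
in hardware by the stimulus isolator is modeled as a symmetric biphasic
split of each pulse — positive then negative half-phase of equal length — so
the signed waveform integrates to zero; stimulation current is set on the
isolator and is deliberately not a software parameter.

## Vision pipeline

Frames are thresholded (`pixel >= T`), components are labeled with
8-connectivity (diagonally touching blob pixels stay one region), and the
largest region's plain (unweighted) binary centroid, normalized by frame
width and height, is the animal's position. Regions below a 5-px area floor
are ignored before largest-region selection to reject single-pixel noise;
area ties resolve to the smallest (y, x) centroid so the pipeline is
deterministic. An empty result flags the sample invalid rather than
inventing a position.

Head direction uses two color markers in separate channels: the angle of the
rear-to-front vector, in degrees [0, 360), measured y-up (pixel y points
down, so the vertical offset is negated). One missing or coincident marker
reports 0 degrees with a single-marker flag — the tracker's documented
fallback — rather than an error.

Auto-calibration lights each wall LED in turn, grabs three frames, takes
their pixelwise median (one frame would suffice on the noiseless synthetic
camera; the median makes the routine robust to a glitch frame), and places a
zone at the detected spot's centroid. No spot above the area floor is a
calibration failure naming the LED; more than one is an ambiguity error —
both conditions abort rather than guessing.

Streamed positions use OSC 1.0 binary framing (address `/position`,
typetags `,ifffi`, payload `frame_index, x_norm, y_norm, angle_deg, valid`).
The payload layout is versioned by the fixed typetag string; invalid samples
keep the last position fix in the payload with `valid = 0`.

## The simulator

The agent is piecewise-linear waypoint pursuit at constant speed with
optional pauses at waypoints, Gaussian positional jitter, and i.i.d.
per-sample dropouts, all driven by one seed — it exists to exercise the
engine and the vision loop deterministically, not to model rodent
locomotion. Real tracking data differ in ways the simulator does not
emulate: autocorrelated speed, body occlusion, reflections, and
near-boundary dithering; passing tests therefore validate the control and
measurement logic, not tracking robustness on real video. The renderer
draws the platform dark (intensity 10), the animal as a bright disk
(radius 6 px, intensity 220) or two colored half-size disks 8 px apart in
head-direction mode, and lit LEDs as 2-px dots; layout positions are
computed in the y-up angle frame and flipped to pixel rows when drawn.

Preset configurations reproduce the published task setups on a 640x480
synthetic camera (platform center (320, 240), LED ring radius 200 px, zone
radius 20 px): spatial reorientation (three zones — a virtual start zone
placed off-frame and advanced with Next Cue, a rewarded zone with a 1.5-s
dwell delay, an end zone — with passthrough advancement), the sequence task
(five distinct perimeter zones, rewarded order 1-2-3-4-1-2-3-5), random
lights (all 32 zones, a drawn sequence of up to 900 elements), OPPA (seven
zones, reward type none — rewards are manual), and the MAT family (eight arm
zones, a center zone, and an off-maze rewarded-control zone that closes
incorrect trials; the egocentric variant has no rewarded zones and uses
manually triggered stimulation). The compliant-agent helper visits the
rewarded list in order and inserts a platform-center detour between repeated
consecutive zones, since a reward can only re-fire after an exit and
re-entry.

## Post-processing

Trials run from a start marker (entry into a start zone, or each Next Cue
press when the start zone is virtual) to the next end-zone entry; unpaired
starts are dropped with a warning. Speed is a central finite difference over
valid samples, optionally smoothed by a centered moving average (default 5
samples), and averaged in bins (default 5 px) of the signed along-track
distance to the reward-zone center — the 1-D projection onto the start-to-end
axis, negative before the zone on the outbound run (the sign convention is
this package's definition; only "position relative to the reward zone" is
inherited). A trial is excluded when its longest tracking gap — time from
the last valid fix before an invalid run to the first after it — exceeds
`max_gap` (default 0.5 s; "too extensive" is otherwise unquantified);
shorter gaps are filled by linear interpolation. The performance criterion
is strict: a session counts only if its percent correct is strictly greater
than the threshold (default 80), and the default window is the *most recent*
n sessions with an any-consecutive-window option, since the original rule
does not say which.

## Problem sizes and numerics

The test suite and the acceptance script run everything at desk scale: 751
samples (25 s at 30 Hz) for the full sequence-task loop, 1,000-sample random
walks for the engine invariants, 50x50 binary frames against the flood-fill
oracle, 240 frames for the end-to-end video recovery, and the full 32-LED
calibration sweep — sizes chosen so the whole suite completes in well under
a minute while still exercising every code path. Angular arithmetic keeps a
1e-9 tolerance on the 360-degree closure of ring layouts; pulse-train totals
are compared to the closed form at 1e-12 relative; event logs are written
with fixed 6-decimal timestamps so repeated seeded runs are byte-identical.
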