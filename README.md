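# mazekit

A headless, hardware-free engine for zone-triggered rodent maze experiments.

Behavioral neuroscience labs run spatial-cognition tasks on open circular
platforms ringed with cue LEDs and reward spouts: software watches the
animal's tracked position, timestamps every entry into and exit from circular
*zones of interest*, arms one rewarded zone at a time according to a
configured sequence, and announces each event to the electrophysiology
acquisition system as a binary TTL word so neural and behavioral data share a
clock. `mazekit` re-implements that control logic as a pure-Python library
that runs entirely at a desk: every task protocol the platform supports —
spatial reorientation on a linear track, a complex eight-item spatial
sequence, random cue lights, object-place paired associates (OPPA), and
map-to-action transformation (MAT) — can be configured, simulated, logged and
analyzed without a camera, an animal or an I/O board.

## What is inside

- **Zone geometry** (`mazekit.geometry`): circular zones with *hysteresis* —
  once the animal is inside, the effective radius grows by a factor
  (default 1.5) so small head movements do not register as false exits; a
  ring layout of 32 evenly spaced wall LEDs; the LED-to-reward-spout map
  (one spout over every fourth LED, eight spouts).
- **Task engine** (`mazekit.engine`): the session state machine. Occupancy
  flags per zone, entry/exit events with their TTL words, one armed rewarded
  zone at a time, dwell-delay gating (the animal must remain in the zone for
  a configured delay to earn the reward), manual *Next Cue* advancement,
  optional uniform randomization of the rewarded sequence, and session
  counters.
- **TTL encoding** (`mazekit.ttl`): zone number 1–32 as 6 big-endian data
  bits, an entry/exit flag bit and a strobe bit, on a virtual 48-line
  LED/event bank; a 16-line valve bank for liquid-reward pulses.
- **Stimulation** (`mazekit.stim`): pulse trains from frequency, duration and
  duty cycle — `floor(frequency x duration)` cycles, each high for
  `duty/100` of its period — edge-triggered launching with a train-length
  lockout, and a charge-balanced biphasic model of the stimulus isolator.
- **Vision** (`mazekit.vision`): threshold -> 8-connected regions -> largest
  region -> centroid -> frame-size normalization; two-marker head direction;
  sequential-LED auto-calibration that places a zone at each detected LED;
  OSC `/position` streaming messages.
- **Simulator** (`mazekit.simulate`): waypoint-pursuit agents with jitter and
  tracking dropouts, a synthetic camera that renders the platform, and
  ready-made presets for every task above.
- **Post-processing** (`mazekit.analysis`): trial segmentation from the event
  log, velocity profiles binned by signed distance to the reward zone,
  lost-tracking exclusion, and the k-of-n performance criterion
  (default: strictly over 80 % correct in at least 3 of the last 4 sessions).

## Worked example

Simulate a full run of the complex spatial sequence task — five zones on the
32-position perimeter, rewarded in the repeating eight-item order
1-2-3-4-1-2-3-5, no dwell delay — with a compliant agent:

```
$ maze run-sim --preset sequence_task --t-max 25 --seed 1 --out demo/
sequence_task: 751 samples, 50 events, 8 rewards -> demo
```

One full traversal of the loop yields exactly 8 reward events, one per
sequence element. The event log carries, for every zone crossing, the TTL
word the acquisition system would have timestamped:

```
t,kind,zone_id,ttl_word,detail
0.000000,led_on,1,,led=1
0.000000,zone_entry,5,00010111,
0.266667,zone_exit,5,00010101,
1.700000,zone_entry,1,00000111,
1.700000,reward,1,,
1.700000,stim_animal,1,,
```

Reading the first entry word `00010111`: data bits `000101` = zone 5, flag
`1` = entry, strobe `1`. The agent starts at zone 5 (the task's start
location), and on entering zone 1 — the armed first element — the reward
fires, the brain-stimulation event is logged, zone 1's cue LED goes out and
zone 2's comes on.

A stimulation train is one command:

```
$ maze stim --freq 100 --duration 0.5 --duty 50
t_on,t_off
0.000000,0.005000
0.010000,0.015000
...
# 50 pulses, total high time 0.250000s of 0.5s
```

`maze calibrate` runs the LED auto-calibration against the synthetic camera,
`maze postprocess` turns event/sample logs into per-trial velocity profiles,
and `maze validate-config` checks a settings JSON file.

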