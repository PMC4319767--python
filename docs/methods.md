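# Methods

## The annotation model

The annotator is a deterministic rule system over kinematic variables,
not a learned classifier.  Its assumptions:

* the stimulus is a rigid cuboid whose pose is given exactly by the
  embedded sensor at its center (local frame: origin at the center, axes
  along the edges, the long edge as local z);
* the world frame is right-handed with z vertical-up and the table
  surface at z = 0 (the tracker's world axes are not otherwise
  constrained, so this is a convention of this implementation);
* units are fixed project-wide: mm for positions and distances, s for
  time, m/s for speeds, deg for angles, deg/s for angle rates, mm³ for
  volumes;
* time intervals are half-open `[t_start, t_end)` and a per-sample label
  applies at the sample's timestamp, which makes durations additive and
  the mask-to-interval conversion exact;
* only the instrumented sites are observable: per hand the index nail,
  index proximal phalanx and thumbnail.  Rubbing with an uninstrumented
  finger is invisible; deformation of the (physically compliant)
  stimulus is observed only through sensor positions entering the
  nominal rigid box.

Positions (never orientations) are filtered before any feature is
computed.  The filter is a 2nd-order Butterworth low-pass at 6 Hz,
applied forward–backward (`filtfilt`).  The zero-phase choice matters:
the criteria are evaluated per timestep, and a causal filter would delay
every feature by a frequency-dependent lag and systematically shift all
annotation boundaries.  The two passes square the magnitude response, so
the single-pass −3 dB point at the cutoff becomes a gain of ≈ 0.5.

Rates of change are central differences on the filtered signals,
one-sided at the two ends; the 6 Hz filtering already suppresses the
noise amplification that differentiation would otherwise cause, so the
rate channels get no additional smoothing.

## Variables: definitions and numerical choices

* **Relative speed** is the absolute rate of change of the Euclidean
  distance between a nail sensor and the stimulus-center sensor (a range
  rate).  This is the literal definition and it has a known blind spot:
  motion at constant distance from the stimulus center (e.g. circling
  it) reads as zero.  A `velocity_norm` mode (norm of the relative
  velocity vector) is available in the config, off by default.
* **Hull size** is interpreted as the *volume* (mm³) of the convex hull
  of the 8 cuboid corners plus the thumbnail point, computed with Qhull.
  "Size" could also have meant surface area; volume is the natural
  reading of a 3-D hull with a containment criterion, and the identity
  "hull volume = cuboid volume iff the thumb is inside or on the box"
  gives a sharp cross-check against the containment test.
* **Surface distance** uses a 5 × 9 point lattice per face (45 points,
  endpoints included, the larger count on the longer in-face dimension;
  odd × odd so face centers and edge midlines are on the grid), 270
  points in all.  The grid distance is an upper bound on the true
  point-to-surface distance; the excess is bounded by half the largest
  grid-cell diagonal (≈ 10.8 mm for the default geometry) and is tested
  against a 10⁴-points-per-face dense grid.
* **Containment** (virtual midpoint within stimulus) is a closed-box
  test in the stimulus local frame: a point exactly on a face counts as
  inside.
* **Index-finger angle** is the geodesic rotation angle between the nail
  and proximal-phalanx orientations, in [0°, 180°], insensitive to
  quaternion sign.  Orientations are used raw; filtering quaternions
  componentwise would not preserve unit norm and the angle-rate
  criterion (< 80 deg/s) tolerates raw orientation data at this sampling
  rate.
* **Lift detection**: the elevation baseline is the median over the
  first 500 ms of the trial; the lift sample is the first one more than
  10 mm above baseline with positive elevation rate.  The method needs
  *some* rule for "when the stimulus is initially lifted"; the 10 mm /
  500 ms values are config parameters (`lift_height_delta_mm`,
  `lift_baseline_window_ms`) chosen at desk scale: 10 mm is well above
  tracker noise yet small against the 80 mm carrying height.

## Criteria details

All printed comparisons are strict (<, >), exactly as typeset; a value
exactly at a threshold never satisfies a criterion.  For Unsupported
Holding the opposite thumb must be *farther* than 20 mm, so a thumb at
exactly 20 mm satisfies neither the "close" nor the "not close" side.

The Pressure reference is captured per hand at the single trial-level
lift event.  "A decrease in hull size prior to crossing the reference"
is implemented as a run-entry test: for each maximal run of samples with
hull < reference, the mean hull rate over the 100 ms
(`pr_decrease_window_ms`) preceding the run's first sample must be
negative, otherwise the whole run is rejected.  This blocks the
outward-pointing-thumb artifact at pickup (hull still shrinking toward
its grip value counts, hull growing does not).  Samples before the lift
(and whole trials without a detected lift) are never labelled PR, since
the reference does not exist yet.

## Post-processing

Per pass: gap filling → minimum-duration pruning → dominance resolution,
and the pass runs twice (`postprocess_passes = 2`) because resolution
can leave fragments shorter than the minimum that only the next pass's
pruning removes.

* Gap filling closes false runs strictly shorter than 50 ms flanked by
  true runs of the *same* channel.  One refinement beyond the bare rule:
  a gap is only filled while no other label sharing the hand occupies
  it, and occupancy counts only runs at least their own EP minimum.
  Without this, the second pass's filling re-merges exactly the gaps the
  first pass's dominance resolution carved out (or is transiently
  blocked by a doomed sub-minimum remnant), and the two-pass output is
  not a fixed point.  With it, the cleaned output provably carries no
  sub-minimum interval and no shared-hand simultaneity, and a third pass
  changes nothing — verified by fuzzing over thousands of random masks.
* Pruning deletes true runs strictly shorter than the per-EP minimum; a
  run exactly at the minimum stays.  The printed range is 17–250 ms
  "depending on EP" without the mapping; the defaults here are LM 100,
  PR 17, UH 250, EN 250 ms — the brief-contact EP (PR) gets the floor of
  the range, the sustained postures (UH, EN) the ceiling, LM an
  intermediate value of one rub stroke — and all four are config values.
* Conflict = shared hand (EN occupies both hands, so it conflicts with
  every unimanual label; left and right unimanual labels of different
  EPs coexist).  At each conflicted timestep only the label ranked
  highest in LM–UH–PR–EN survives.  By default the loser is cleared over
  the overlapping timesteps only; clearing the loser's whole interval is
  available as `conflict_mode: interval`.

Durations are counted in samples (a run of k samples lasts k/fs), and
interval endpoints are emitted as sample_index / fs so abutting runs
produce exactly matching boundaries.

## Rater comparison

Timewise agreement samples both tracks on a common grid (1/300 s step by
default); a rater's state at a timestep is the exact set of active
(EP, hand) labels, and agreement is the percentage of timesteps with
identical sets.  Two defaults are worth making explicit: the hand is
part of the state (an LM-left vs LM-right frame is a disagreement), and
a timestep where neither rater marks anything counts as agreement —
manual raters annotated seven hand-specific behaviors, and "agreeing
about the presence of all EPs" includes agreed absence.  Both choices
are config switches (`agreement_hand_sensitive`,
`agreement_count_coblank`) for sensitivity analysis, since the absolute
agreement level depends on them.

Main/secondary EPs are the two (EP, hand) labels with the largest total
duration; ties break by the dominance ranking, then lexicographic hand
order.  The main/secondary overlap between the automatic rater and the
humans compares EP identity ignoring the hand (hand-sensitive comparison
available); blanks never match.  The random baseline annotates one
uniformly drawn label over the whole trial, derives its main EP from
that single label (secondary blank), and is averaged over 10 independent
runs.

## The synthetic generator

The renderer emulates the data-gathering setup: a cuboid stimulus
(outer dimensions 52 × 62 × 120 mm — the printed 30 × 40 × 120 mm core
plus an equal covering thickness on the four long faces sized to the
instrumented stimulus's 382 cm³ outer volume; configurable) standing on
the table, hands starting ≈ 20 cm to either side, a bimanual pickup,
lift to 80 mm, one scripted exploration episode (3.2–5.2 s of an 8 s
trial in the canonical builder), replacement and release.  Sensor
streams are generated at 300 Hz from keyframed poses with smoothstep
transits routed around (never through) the cuboid.

Behavior templates are the minimal motions meeting each criteria set:
LM is a sinusoidal rub of the index nail along the long axis, 6 mm off a
face and offset from the face center so the rub modulates the
center distance (15 mm amplitude at 5 Hz ⇒ 0.47 m/s peak rub speed);
PR presses the thumb 3 mm into the nominal box through a 120 ms smooth
ramp; UH is a static one-hand grip with the other hand back at its
start position; EN is both hands statically straddling the box with
midpoints inside.  Infeasible scripts (e.g. an LM rub whose
amplitude × frequency cannot exceed the 0.10 m/s gate) are rejected at
build time.

Two overlays keep unscripted stretches clean.  A grip-adjustment jitter
on the holding thumb (outward-only radial bumps, ≈ 0.09 m/s peak — above
the 0.05 m/s low gate, below the 0.10 m/s high gate) runs during
transports where only that hand holds the stimulus, so Unsupported
Holding cannot latch onto the carry phases while Lateral Motion is never
triggered; the sub-gate windows around its speed reversals are shorter
than the minimum durations.  An index-orientation wiggle on the lifting
hand (± 25° at 1.5 Hz ⇒ 235 deg/s peak angle rate) runs while both hands
grip outside scripted EN episodes and blocks Enclosure the same way.
Both overlays are phase-locked to zero rate at the scripted episode's
boundaries, bounding the onset/offset bias of the recovered episode to
≈ 30–45 ms, inside the gap-fill/minimum-duration scales.  The grip also
relaxes from a 4 mm to a 6 mm standoff during the lift ramp itself, so
each thumb hull is strictly increasing from the moment the Pressure
reference is captured — without that, the strict hull comparison latches
onto numerical wobble of an exactly-constant hull.

Noise is additive i.i.d. Gaussian per axis and sample on positions
(optionally small random rotations on orientations), seeded; the
pipeline's 6 Hz filtering is the intended defense.  What the generator
does *not* emulate: tracker-specific noise spectra and drift, soft-body
deformation of the compliant stimulus, biomechanical hand constraints,
multi-finger contact, or natural behavioral variability.  Passing the
recovery tests therefore shows the pipeline implements its rules
correctly on motions designed to satisfy them — it does not certify
performance on human recordings.

One honesty caveat is structural: under the range-rate definition of
relative speed, any bounded periodic rub crosses zero range rate twice
per stroke cycle, so the LM speed gate necessarily drops out for
~ 25–45 ms around each stroke reversal no matter the template.  This is
exactly the dropout the 50 ms gap filling exists to repair.  The
renderer/classifier cross-validation therefore asserts full-criteria
coverage ≥ 95% for PR, UH and EN, and for LM asserts the distance and
opposite-thumb components at ≥ 95%, the full criteria on a clear
majority of samples, and the gap-filled LM channel at ≥ 95%.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale: 8 s trials at
300 Hz (2400 samples), 20 noise-free trials (five per EP, consecutive
seeds) for ground-truth recovery with frame F1 ≥ 0.9 and onset/offset
error ≤ 60 ms; hull volumes checked against a scrambled-Sobol
quasi-Monte-Carlo oracle (2¹⁶ samples, Delaunay membership) at < 1%
relative error over 50 random thumb placements; grid distances against
a 100 × 100-per-face dense grid at ≤ half the coarse cell diagonal over
100 random queries; agreement against a python-set brute-force
recomputation (exact) on 50 fuzzed track pairs; post-processing
invariants over 1000 fuzzed masks; the random baseline over 7000 seeded
draws with exact binomial 3-SD bounds.

## Known limitations

* The four-EP vocabulary cannot express other exploratory behaviors
  (contour following, part motion testing, …); unmodelled behavior is
  simply left blank.
* Range-rate relative speed underestimates tangential rubbing that
  happens to preserve the distance to the stimulus center; the
  `velocity_norm` mode trades this for sensitivity to rigid transport.
* The criteria thresholds are constants per configuration, not per
  participant; what is fast for one person may be slow for another.
* The Pressure reference assumes one lift per trial; re-grasps after a
  put-down keep the original reference.
* With fewer than ~ 2 samples per minimum duration (fs well below
  300 Hz), the strict-boundary semantics of gap filling and pruning
  become coarse; the implementation assumes the nominal 300 Hz regime.
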