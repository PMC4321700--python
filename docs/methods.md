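# Methods

This note records the definitions the package implements, the estimator
choices made where a definition is silent, and what the synthetic
generators do and do not emulate.

## Data model and conventions

Tracks are planar centroid positions in millimetres at a nominal 1 s
capture interval; head landmarks are sampled every 500 ms; all angles are
degrees. Whether the ventral side lies to the left of the heading is
tri-state metadata (`True`/`False`/unknown). Signed quantities (curving
rate, head angle) are ventral-positive whenever that metadata is present;
with unknown orientation they are reported counter-clockwise-positive and
the series carries `sign_convention="ccw_positive"` — anatomical sign
cannot be inferred from centroid geometry alone. Tracks of animals that
came within `min_separation_mm` (default 1.0 mm, about one body width; no
canonical value exists) of another animal are flagged excluded rather than
deleted. Duplicate timestamps keep the first sample; off-nominal sampling
intervals are logged, not fatal.

## Curving rate

The curving rate is the change of direction per unit advancement, deg/mm.
Estimator: samples are first passed through a greedy minimum-step filter
(`min_step_mm`, default 0.05 mm) so sub-pixel jitter cannot produce wild
headings; each retained step's heading is the direction of its
displacement; at each interior vertex the heading difference, wrapped to
(−180°, 180°] with exact reversals broken toward +180°, is divided by the
mean of the two adjacent step lengths (a centred per-advancement
estimate — the denominator choice is not canonical and is recorded in the
series). The same mean adjacent length is the weight in every summary, so
the weighted sum of a series is the track's net signed turning.

Fixed-time means are anchored at the track's first sample (default window
1200 s = 20 min of tracking). Fixed-distance means truncate the track at
arc length L0 (default 30 mm), the final point linearly interpolated along
the last segment. Histograms are path-length-weighted, half-open bins
aligned so 0 deg/mm is a bin edge; the bin width has no canonical default
and must be chosen by the caller.

Numerical note: on a circle sampled at arc steps Δs, chord-based headings
overestimate the arc-defined rate by ≈ (Δs/R)²/24 relative (4×10⁻⁴ at
0.5 mm steps on a 5 mm radius); tests tolerate this.

## Coarse-grained path statistics

For δ in (0, L0], dividing points are placed at arc lengths 0, δ, 2δ, …
along the first L0 of track (positions interpolated on the polyline, never
snapped to samples), with the point at arc length L0 always appended:
the final partial sub-trajectory contributes one chord, so L_δ spans the
full L0 and is continuous in δ. L_δ is the summed chord length;
ratio = L_δ/L0 obeys 0 < ratio ≤ 1 and L_δ ≥ |end − start|.
The default δ grid is 10 points log-spaced from 0.5 mm to L0 (ratio curves
are viewed log-log; no canonical grid exists). Cohorts are summarized by
the per-δ median and first/third quartiles of log10(ratio) with
linear-interpolation ("type 7") quartiles, recorded as such; an n = 1
cohort reports q1 = q3 = median.

## Loop detection and CL classification

Definitions retained from the phenotype: a loopy segment forms a closed
circle with diameter < 10 mm; an animal is CL when loops cover ≥ 30% of
its track (the inclusive ≥ form); "strong" animals loop essentially
continuously, operationalized as coverage ≥ 0.95 to tolerate closure gaps.
Coverage is measured by path length (not time). The remaining thresholds
operationalize what was originally scored by eye and are all configurable
and reported: a closure is a pair of path positions ≥ 3 mm of arc apart
and ≤ 0.5 mm apart in space; the enclosed sub-path must also accumulate
≥ 330° of net signed turning (rejecting out-and-back excursions); its
minimal enclosing circle — computed exactly via GEOS with bounding-box
screens — must be under 10 mm. The scan is greedy earliest-closure-first:
from each vertex the earliest qualifying closure opens an interval and the
scan resumes at its end; overlapping or abutting intervals merge while the
merged sub-path still fits the diameter bound. Because a straight approach
tangent to a loop can pass within the closure tolerance slightly before
the geometric tangent point, detected intervals can start up to ~1 mm
early; loopy fractions carry that granularity.

Assay proportions group reports in input order into plates of 10 worms
(configurable) and report per-assay percentages, their mean, and the
pooled percentage.

## Head-bend kinematics

The head angle is the angle between the centroid→terminal-bulb vector and
the terminal-bulb→nose-tip vector, signed by their cross product and
remapped to ventral-positive; it is invariant under rigid motions and
uniform scaling, and mirror reflection negates it. Frames with coincident
landmarks (< 10⁻⁶ mm apart) are dropped and logged. Actual timestamps are
used; frames are not re-interpolated onto an exact 0.5 s grid. A bend is a
local extremum with prominence ≥ 10° (scipy `find_peaks`; no operational
definition of "bend" exists upstream, so the prominence is configurable
and reported); positive extrema are ventral bends, negative dorsal, and
the dorsal mean is emitted both signed and as a magnitude since either
reading of "larger dorsal bends" may be wanted.

## Fluorescence quantification

Background correction subtracts the mean of exactly three background
points from each ROI mean, before any ratio is formed — pre-formula
correction is the only ordering that cancels a camera offset from all
three terms (an invariance the tests assert on random records). The rate
of change is (after − bleached)/(intact − bleached); it requires the
bleach to have removed at least 1% of the corrected intact intensity
(`InsufficientBleachError` otherwise), flags values outside [0, 1], and
warns when the bleached/intact ratio leaves the expected 0.5–0.7 band.
The recovery ratio is rate − mean(control rates) + 1, with control rates
averaged after background correction (the alternative ordering is not
meaningfully different for offset-free data and is not offered). Puncta
are supplied as a table from external segmentation; corrected intensities
are clipped at 0 with a warning, and an empty table yields mean 0 with
n = 0 rather than an error.

## Synthetic generators

`simulate_trajectory` is a correlated random walk: per step of length
ds = speed·Δt the heading changes by (regime bias + Gaussian noise) · ds,
with the bias a curving rate in deg/mm — matching the per-advancement
definition, so the analysis recovers the programmed bias directly (cohort
mean within ±10% at noise ≤ |bias|, asserted). A noise-free constant bias
b closes onto a circle of diameter 360/(π·|b|) mm. Regimes follow a
two-state Markov chain ("normal"/"loopy") toggling with `bout_switch_prob`
per step; `start_regime` selects the initial state, so a mutant-like
animal that loops from the outset is configured with `start_regime="loopy"`.
Defaults: speed 0.15 mm/s, 1 s steps, 1200 s duration (a 20-minute
tracking session; tracked speeds are not standardized, so the speed is a
configurable placeholder of realistic magnitude). The ventral side is set
to the left of the heading so positive bias means ventral-ward curving.

The generator emulates the statistical structure the estimators assume —
constant speed, per-step turning, Markov bouts — and deliberately not:
reversals/omega turns, speed fluctuation, plate-edge interactions, or
posture. Passing tests therefore validate the estimators' algebra and
calibration, not tracker noise robustness beyond the min-step filter.

`simulate_head_wave` programs an asymmetric oscillation (positive
half-cycles scaled to the ventral amplitude, negative to the dorsal; the
default 4 s period puts the 0.5 s sampling grid exactly on the extrema)
and realizes it through landmarks — centroid at the origin, bulb 1 mm
along +x, nose 0.5 mm from the bulb rotated by the programmed angle — so
the head-angle computation inverts it exactly at zero noise.

`simulate_fluorescence` draws per-animal bleach retention uniformly from
0.5–0.7 and recovers a programmed fraction of the bleached-away signal;
a constant background level (default 10) is added to every ROI value and
reported at the background points, so the analysis must actually perform
the correction to recover the programmed fractions exactly at zero noise.

All generators are pure functions of their configs; the same seed gives
bitwise-identical output. Cohort seeds derive deterministically from a
master seed.

## Problem sizes and limitations

Default analyses run on 1200-step tracks (30–180 mm of path), cohorts of
30 animals per group, and 10–25 fluorescence records — sizes at which the
full suite and the acceptance script each complete in seconds while the
Monte-Carlo assertions (bias recovery, cohort separation) have comfortable
margins. Known limitations: the loop detector's interval boundaries are
closure-tolerance-granular (above); curving estimates degrade for step
lengths approaching the loop radius; coarse-graining assumes the track is
dense relative to the smallest δ; and none of the modules attempt to infer
ventral orientation, reversals, or posture from centroid data.
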