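# Methods

## Experimental model

The toolkit targets the standard automated imprinting cage: a rectangular
arena (default 90 cm between screens, 60 cm wide) with a monitor at each
short wall as the only light source, filmed from above. An experiment is a
grid of days × sessions; each session runs an imprinting phase (one image
on one screen, the other dark), a dual-choice test phase (one image per
screen), or both, separated by dark pauses. All times are absolute seconds
from experiment start; "days" are logical blocks, not wall-clock dates.

Because chicks perceive flickering light as continuous only above roughly
115 Hz, the configuration validator rejects any display refresh below that
value; the package default is 120 Hz. This matters both for the ambient
light (the screens are the illumination) and for the frame rate at which
stimuli are presented.

## Scheduling and side balance

Side assignment is a seeded shuffle of a maximally balanced left/right
multiset over the *whole experiment* per stimulus set (not per day): with
equal session durations this balances exposure time exactly, up to one
session when the count is odd. The surplus side for odd counts is itself a
seeded draw, so no side is structurally favoured. A cap on consecutive
same-side runs exists as an option but is off by default — the balanced
multiset already bounds runs — since run constraints change the assignment
distribution.

Per-session stimulus choice defaults to uniform sampling **with**
replacement from the set ("a fresh random image each session");
without-replacement cycling is available as `stimulus_sampling="cycle"`.
Pauses are explicit dark events, so the audit log reconstructs the screen
state at any instant. The log's canonical form is CSV (byte-identical for
identical config and seed, floats written with `repr` so the round trip is
lossless); the Excel export mirrors the same columns.

## Motion conventions

Translatory motion is `x(t) = center + A·sin(2πt/T)`: the image starts at
the centre moving in +x, and both position and speed are sinusoidal. `A`
is the maximum displacement from the centre (peak-to-peak `2A`). Flicker
is a square wave starting visible. Both conventions are arbitrary where
the underlying behaviour is symmetric; they are fixed and documented so
frame logs are reproducible. Events are sampled half-open
`[start, end)` at `round(duration × refresh)` frames, which keeps
contiguous events from double-emitting boundary frames and keeps frame
counts within one frame of the nominal duration. Phase values within
~1e-9 s of a flicker boundary are snapped onto it so that frame times
which are not exactly representable in binary (e.g. 1.4 s) land in the
intended half-cycle.

## Numerosity stimuli

Arrays are homogeneous: `n` elements of area `TA/n` each. Discs use radius
`sqrt(TA/(nπ))`; rasterization makes the realized area deviate from TA by
up to a few percent at small radii, so the package-wide tolerance on
measured area is 10 %. Integer-sided squares are available when exact
pixel counts are needed. Centres come from seeded rejection sampling with
a minimum edge gap (default 2 px) and a 10⁴-try budget; exhausting the
budget raises a capacity error naming the constraint rather than silently
overlapping elements. The measurer is deliberately independent of the
generator — 8-connected flood fill for the count, pixel count for area,
convex hull of the foreground for density and span — so it can serve as an
oracle in tests and in the acceptance script. Canvas size (800 × 600) and
the white-on-black channel choice are package defaults, not measured
values.

## Pose tracks

Input is the DeepLabCut CSV dialect (header rows scorer/bodyparts/coords,
x/y/likelihood per bodypart). Cleaning masks points with likelihood below
0.9 (configurable) by setting their coordinates to NaN, then linearly
interpolates interior gaps up to one second's worth of frames
(configurable); interpolated frames have their likelihood raised to the
threshold so cleaning is idempotent, and longer gaps stay masked and are
excluded from all durations. Pixel→cm conversion is a single isotropic
scale plus origin offset: with the camera ~105 cm above a 90 cm arena,
perspective error across the floor is below behavioural precision, so a
homography is not fitted. Gaze analysis requires beak and both eyes;
`head_center` is synthesized as the eye midpoint when not tracked.

## Behavioural metrics

Stimulus zones default to arena thirds (30 cm deep); the depth is a
configuration parameter echoed into every output row, since published
zone sizes vary. First choice requires an *entry* — a transition into a
stimulus zone — not a starting position. The preference index is
`t_target/(t_target + t_other)`; when the chick visits neither stimulus
zone the index is NaN with an explicit `preference_defined=False` flag,
never a silent 0.5.

Eye use is classified from the signed angle between the head axis (eye
midpoint → beak) and the bearing to a point on the stimulus screen at the
chick's own y (the screen spans the wall; a fixed point can be substituted).
The binocular half-angle (default 15°) and lateral limit (default 150°)
are calibration placeholders — published angular values for this paradigm
are not established — and both are carried in the output metadata. The
left/right decision compares the bearing's sign with the side of the
anatomical left eye, which makes the classifier exactly mirror-symmetric:
reflecting the scene (and swapping the eye labels, as a mirror does) swaps
the monocular labels and preserves the binocular/none classes, a property
the tests check on random configurations. Degenerate head geometry
(coincident keypoints) classifies as `none`.

Activity sums Euclidean head steps whose two endpoint frames are both
unmasked; mean speed divides by the summed duration of counted steps only,
so dropout does not dilute speed.

## Synthetic chicks

The simulator exists to validate the pipeline, not to model chick
cognition. It is a bout-structured walk: travel toward a goal anchor
placed centrally in one stimulus zone, then dwell there under an
Ornstein–Uhlenbeck-style pull (dwell ~15 s ± 20 %), then redraw the goal —
target side with probability `p`, the other side otherwise. Dwell bouts
are i.i.d. and equally long on both sides, and zone *entries* are equally
frequent on both sides (an entry requires a side switch, and switches in
the two directions alternate), so the expected share of stimulus-zone time
at the target equals `p` by construction. This removes the need for a
pilot-simulation calibration of a drift coefficient; the tests verify the
calibration empirically (mean recovered PI within 0.05 of `p` for
`p ∈ {0.2, 0.5, 0.8}`). Head keypoints ride on a rigid triangle (eyes
1.5 cm apart, beak 2 cm ahead of the eye midpoint — plausible chick-scale
fixture constants) oriented along the exponentially smoothed velocity plus
Gaussian heading noise; a seeded fraction of frames is emitted with
likelihood 0.1 to mimic tracking dropout. Walls reflect; every draw comes
from one seeded generator, so identical parameters give byte-identical
CSVs.

What the simulator does **not** emulate: pecking, resting bouts, thigmotaxis,
learning dynamics within or across sessions, perspective or lens
distortion, or correlated (burst) tracking failures. Passing the
end-to-end recovery tests therefore shows the *pipeline* is unbiased and
correctly calibrated, not that it is robust to every artefact of real
video tracking.

## Problem sizes and numerical choices

The end-to-end recovery suite uses 50 sessions of 600 s at 30 fps per
preference level, the scale at which session-mean preference estimates
have a standard error well below the 0.05 acceptance band; unit tests use
shorter sessions at 15 fps where only calibration, not power, is at stake.
Uniform-sampling checks use 5000 sessions with a χ² test at α = 0.01.
Quadrature checks of the motion engine use 10⁴ samples per period.
Floating-point tie-breaks (flicker boundaries) are snapped as described
above; all other comparisons in tests use standard relative tolerances.

## Known limitations

- No live rendering or v-sync guarantees: the frame log is the ideal
  output a psychophysics toolbox would be asked to realize.
- Single-animal tracks only; multi-animal disambiguation is out of scope.
- The pixel→cm model is isotropic; fisheye or oblique cameras need
  external rectification first.
- Eye-use thresholds are placeholders awaiting empirical calibration;
  conclusions driven by the binocular/monocular split should be checked
  for robustness across threshold choices (every output row records them).
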