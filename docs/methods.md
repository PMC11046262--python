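# Methods

## Engagement classification

The classifier operates per frame and per camera in raw pixel coordinates
(origin top-left, y down). A marker observation carries four corner points
in the detector's canonical order (pattern top-left first, then clockwise).
Pose is purely 2D: the center is the corner mean, and the heading is the
unit vector from the center to the midpoint of the *front* edge — the edge
physically nearest the animal's nose, selected by the `front_edge` index
(0–3) because mount orientation varies between rigs.

Yaw is measured against the chamber's module wall, configured per camera as
a directed segment plus an `interior_hint` point that orients the wall
normal. With wall direction `w` and toward-wall normal `n`,
`yaw = atan2(h·n, h·w)` in degrees: 90° is facing the wall squarely, 0°/180°
graze along it, negative values point away. The engaged window
[`yaw_min`, `yaw_max`] = [5°, 175°] is closed — both endpoints count as
engaged. Note the sign of a yaw *change* under a fixed rotation of the
heading depends on which side of the wall the interior lies (the `(w, n)`
frame may be left- or right-handed in image coordinates); the window is
symmetric, so classification is unaffected.

The ROI gate tests the marker *center* (not its corners) against each of
the camera's ROI polygons; the boundary counts as inside, erring toward
engagement the same way the wide yaw window does. A camera that appears in
the data without a configured ROI/wall is a configuration error, never a
silent distracted.

Trial scoring follows the any-frame rule: an active trial is engaged iff at
least one frame inside `[start, end)` classifies engaged on any camera. A
trial with zero detected frames (total occlusion) scores distracted — the
conservative default, since non-detection is indistinguishable from the
animal hiding the marker; `TrialScore.n_frames_detected` lets a caller
exclude such trials instead. Inter-trial frames are classified only for the
live annotation colors (active: green/yellow; inter-trial: purple/pink) and
never scored.

## Detection

Markers are 6×6-module square patterns: a one-module black border around a
4×4 payload, printed with a one-module white quiet zone so the border stays
separable from dark fur or flooring. The dictionary of 50 payloads is
generated deterministically under a minimum Hamming distance of 4 between
any two codes across all four rotations *and* between each code and its own
rotations, so identity and orientation are unambiguous under one-bit read
errors.

The detector thresholds the frame (Otsu), extracts connected dark
components, fits a quadrilateral to each component contour (greedy
farthest-point corner seeding, rejected unless every contour point lies
near the quad outline), rectifies the 6×6 grid with a projective transform,
reads the payload (median of 9 samples per module, adaptive mid-level
binarization), and matches it against the dictionary under all four
rotations; the matched rotation re-indexes the corners into canonical
order. Corners are then refined to subpixel precision by intersecting
total-least-squares lines fitted to the contour points of each edge
(excluding 15 % at each end, where blur rounds the corners). On rendered
frames this recovers planted corners to ≲ 1 px and planted yaw to well
under 2° for markers ≥ 30 px across.

Multi-camera fusion pairs frames by nearest timestamp within half a frame
period (the median inter-frame interval by default) — index-based pairing
would break under real capture-clock drift. Fused records take the union of
observations (logical OR of detection); unpairable frames are kept as their
own records with a warning and counted per camera. The frame account
(camera-1 only / camera-2 only / both / neither) always partitions the
paired frames, and fused coverage can never fall below either camera's own
coverage.

## Engagement dynamics

The probability-of-engagement trace uses a *causal* rectangular window
`(t − L, t]`, so the estimate at time `t` depends only on the preceding
`L` minutes and can be computed live during a session. Defaults: `L` = 5
min, step 1 min, threshold 50 %. Trials enter the window by their active
period's *start* time. Startup windows (`t < L`) are truncated at the
session start and flagged, not skipped. Windows holding no trials yield
missing values, never 0 % — a spurious 0 % would immediately trigger the
disengagement rule. Disengagement is the first defined window strictly
below threshold (`min_consecutive` raises this to a run of windows; default
1, i.e. first crossing). With dense trials and a hard engaged→distracted
switch at τ, the first crossing lands where a majority of the window's
trials post-date τ, so the detected time always lies in [τ, τ + L] with
resolution equal to the step; for the standard 9 s trial cadence and a
switch at 70 min that is exactly 73 min.

## Validation metrics

Accuracy, precision, sensitivity, specificity and F1 are reported as
percents, MCC on [−1, 1], engaged = positive. F1 is computed as the
harmonic mean of precision and sensitivity on fractions, then scaled to
percent (algebraically `2·TP/(2·TP+FP+FN)·100`). Zero-denominator
conventions: precision/sensitivity/specificity are reported missing when
their denominator is empty; MCC is 0 when any of its four marginal sums is
zero (the standard convention — note a matrix like TP=TN=0, FP=FN=5 has
*nonzero* marginals and MCC exactly −1). Display rounding is one decimal
for percents and two for MCC; raw values are preserved in JSON output. A
confusion matrix can also be reconstructed from published marginals (trial
total, reference positives, predicted positives, FN), which determine it
uniquely; infeasible (negative-cell) marginals are rejected.

The blur-velocity model `v = k · fps · FOV/resolution` converts a linear
blur-kernel length to the head speed producing it: with 60 fps, a 42 cm
field of view and 1920 px width, a 2 px kernel corresponds to ≈ 3 cm/s
(reliable tracking below this) and 6 px to ≈ 8 cm/s (detection fully
deteriorated).

## Synthetic sessions

The simulator emulates the study conditions: 6 s active trials alternating
with 3 s inter-trial periods; 60 fps capture (configurable); one or two
cameras; a 15 mm-class marker rendered at 48 px default in a 640×480 frame.
Latent engagement is generated *per trial*, not as a per-frame Markov
chain — the simplest process matching the per-trial scoring granularity: a
two-state model, engaged until an optional planted `disengagement_minute`,
distracted after. The per-trial engagement probabilities in the two states
default to (1, 0), the deterministic case; label noise is opt-in because
the planted changepoint then stops being exactly recoverable. Engaged
trials place the marker inside the ROI with yaw drawn 10° inside the
engaged window; distracted trials violate the ROI gate and the yaw gate in
equal proportion, so both gates are exercised. Per-frame pose jitter
(σ = 1.5 px, 2°) is clamped so it never carries an engaged pose across a
gate. Per-camera dropout deletes observations independently per frame;
ground-truth trial labels come from the latent (pre-dropout) frames by the
same any-frame rule.

What the simulator does *not* emulate: fur/lighting appearance, real
occlusion geometry (dropout is i.i.d. rather than burst-correlated),
camera-clock drift (synthetic streams share exact timestamps), perspective
foreshortening, and scorer disagreement in the reference labels. Passing
tests therefore demonstrate the correctness of the pipeline's logic and
geometry, not field performance on real video.

The renderer rasterizes the module grid at 16× supersampling with a mild
Gaussian (σ = 1.2 hires px) standing in for print/optics softness, maps it
into the frame with an affine transform, and composites over a uniform
background; motion blur is a normalized line kernel of the requested pixel
length along the heading. It returns the planted border corners, so
detector accuracy is measured against ground truth rather than
self-consistency.

## Problem sizes and numerical choices

Long-horizon dynamics checks (the 100 random-changepoint recoveries) use
the trial-label generator directly — frames add nothing to a window
statistic over trial labels. Frame-level end-to-end checks run at 10-20 fps
rather than 60: the any-frame rule makes trial labels invariant to frame
rate in the noiseless case, and lower rates keep full-session simulations
cheap. Default marker size (48 px) sits comfortably above the ~30 px floor
where subpixel corner recovery starts to degrade. Candidate quads below
64 px² of dark area are discarded as noise; payload read-out requires a
0.15 contrast span between the darkest and brightest module before
binarizing, so flat dark blobs are rejected rather than misread.

## Known limitations

- Strictly 2D: no camera intrinsics, no 3D pose; yaw is an image-plane
  angle, biased for strongly tilted head postures.
- The classifier cannot distinguish distraction behaviors (grooming,
  rearing, itching) that happen to hold an engaged pose inside the ROI;
  such frames count as engaged, which is the main false-positive mode of
  this class of system.
- The frame account is defined for one or two cameras; more cameras fuse
  but are not tallied pairwise.
- Video containers are read only where the imaging backend supports the
  codec; directories of PNG frames are the portable input.
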