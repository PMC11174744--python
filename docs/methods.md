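# Methods

This note records the models, parameter choices and numerical conventions
behind `gaitpix`, and what the synthetic-data results do and do not show
about real captures.

## Coordinate and data conventions

Landmarks live in image coordinates: pixels, origin top-left, x rightward,
y downward, 0-based frame indices. The vocabulary is fixed to the twelve
points the pipeline needs — `head_top` and `nose` (unsided), plus `hip`,
`knee`, `ankle`, `heel`, `toe` per side. Adapters may map a full 33-point
pose-estimator skeleton onto it. Depth is carried in the data model but
ignored by all kinematics: subjects are assumed sagittal to the camera, and
all angle and length computations are planar.

Detections with visibility below a configurable floor (default **0.5**) are
loaded but treated as missing. `interpolate_gaps` fills missing runs of at
most `max_gap` frames linearly against timestamps and flags them imputed;
longer runs and runs touching the sequence boundary stay missing. The
operation is idempotent, and downstream modules follow a strict
missing-in → missing-out policy (no hidden imputation).

CSV round-tripping is exact at the binary-float level: floats are written
with shortest-repr formatting and parsed with round-trip precision, because
the default 16-significant-digit writer and the fast float parser each lose
an ulp on some values.

## Joint angles

The interior angle at a joint vertex is computed from the arccos of the
normalized dot product, clipped to [−1, 1]; it lies in [0°, 180°] with 180°
= full extension, and is invariant under translation, rotation, reflection
and uniform scaling — hence identical in pixel and metric coordinates.

Smoothing is a centered moving average with edge truncation; the default
window is **5 frames (0.2 s at 25 fps)**, a light filter that suppresses
pixel jitter without flattening the angular excursions at these walking
speeds. The window must be odd so the filter introduces no phase lag.
Resampling between timebases is linear, with missing spans propagated
rather than bridged, and extrapolation refused.

Open choices resolved here: the ankle angle uses the raw toe landmark for
the instep ray (not a foot midline), and the filter is centered (not
trailing); both alternatives were considered and the simpler image-pipeline
convention chosen.

## Scale calibration and anthropometry

The marker's pixel side is the mean of its four edge lengths, which is
first-order robust to mild perspective; the scale across observations is
the median, robust to isolated corner-detection glitches. The dispersion
(coefficient of variation of per-observation scales) is reported so users
can detect unstable marker tracking. No homography or lens-distortion
correction is attempted — out of scope.

Anthropometric lengths are per-frame Euclidean pixel distances × scale,
averaged over frames, taken only when the capture is static: the median
per-frame landmark displacement must stay below **2 px/frame** (the
threshold is ours; static capture is part of the protocol). Stature is
measured from the highest head landmark to the lowest foot landmark, with a
configurable crown-correction factor (default **1.0**) because common pose
skeletons have no crown-of-head point; users calibrating against true
stature should fit this factor once per skeleton.

Reported table values are rounded with decimal round-half-even on the
value's shortest decimal representation (so a mean of exactly 91.025 prints
91.02); a truncation mode is available because some published tables are
consistent only with truncated cells. Sample averaging accumulates in
decimal on the printed representations of the samples, so reporting ties
are preserved exactly. Full precision is always kept internally.

## Gait-phase state machine

Ground contact per landmark (heel, toe) uses hysteresis: contact engages
within `contact_epsilon` **(0.05)** leg lengths of the ground line and
releases beyond `release_epsilon` **(0.10)**. Normalizing by the leg length
in pixels (median hip-ankle distance) makes the thresholds invariant to
camera distance; the hysteresis band is an order of magnitude wider than
typical landmark jitter, which prevents contact chatter. The ground line is
the **0.95** quantile of observed heel heights — high enough to track the
floor, robust to the minority of swing-phase samples.

Events: heel strike = heel contact with the toe still up; foot flat = toe
contact while the heel is down; midstance = the contralateral ankle crosses
the stance ankle during foot-flat; heel off = heel release while the toe is
down; initial swing = toe release with the heel up; mid swing = the swing
ankle crosses the stance ankle. Crossings are sign changes of the
inter-ankle horizontal offset, so walking direction does not matter.

The sequential-flag rule admits an event only if the previous phase of the
cycle was the last event emitted on that side (the first event of a side is
exempt, since a capture can begin anywhere in the cycle). This is what
debounces contact flicker: a one-frame heel bounce after a heel strike
produces a contact transition whose phase predecessor has not fired, and it
is dropped. `min_event_gap` (**0.2 s**, roughly the physiological minimum
phase spacing at 1.0–1.5 km/h) additionally debounces repeats of the *same*
phase on the same side. The gap is applied per (side, phase) rather than to
consecutive events of any phase: legitimate adjacent phases (heel strike →
foot flat) can fall within 0.2 s of each other at these speeds, and an
any-phase gap would silently break the sequential chain for the rest of the
cycle, whereas same-phase repeats closer than a full cycle are always
artifacts.

Step length is sampled at foot-flat — maximally stable double support — as
the horizontal distance between the two mid-foot points (midpoint of heel
and toe). Traveled distance defaults to steps × mean step length, matching
treadmill captures where the subject is stationary in frame; overground
analyses should use the cumulative mode. The pedometer counts heel strikes
of both feet.

## Synthetic gait model

The simulator emits the exact CSV streams the pipeline consumes, plus
ground truth. Defaults are the study conditions: 25 fps, 44 cm steps at
38 steps/min (≈1.0 km/h), thigh 45 cm, shank 46 cm, foot 25 cm, stature
170 cm, scale 0.4 cm/px, treadmill mode, 10 cm marker.

Rather than driving the leg chain with joint-angle templates, foot
trajectories are constructed directly and the knee follows from two-link
inverse kinematics. Each leg's cycle is: heel rocker (0–10%, foot rotates
flat from 20° dorsiflexion), flat foot on the belt (10–62%), toe rocker
(62–70%, heel pivots up to 35° plantarflexion), swing (70–100%, smoothstep
return with a 10 cm lift bump). Legs are phase-shifted by half a cycle.
This construction makes the planted quantities exact rather than
approximate: stance feet ride the belt, so the heel-to-heel distance during
double support equals the configured step length to machine precision, and
both feet are simultaneously flat for a 2%-of-cycle window each step (the
toe rocker starts after the contralateral landing rotation ends). During
the landing rotation the heel slides slightly forward so the foot
*midpoint* stays belt-anchored — a heel-rocker roll — which is what makes
the mid-foot step-length measurement exact at foot-flat events.

The strike position sits forward of the stance midpoint (at `0.62 × step
length` ahead of the pelvis) so the leg reaches its maximum extension
exactly at touchdown; the hip height is solved so that maximum extension is
**99.9%** of thigh+shank, giving heel-strike knee angles of ~172° (above
the 168° seen at heel strike in slow treadmill walking). Knee flexion in
this stylized gait is deeper at mid swing (~100°) than in physiological
walking (~120°); angle *recovery* tests are unaffected because truth and
measurement share the geometry, but absolute angular ranges should not be
read as normative.

Ground-truth angles are computed from the noiseless landmark geometry with
the same interior-angle operation the pipeline uses — truth and pipeline
can disagree only through noise, never through convention. Ground-truth
events are placed at the analytic sub-phase boundary times (nearest frame);
the detector's events differ by the small threshold-dependent lead/lag, so
tests compare orders and counts, not instants. The capture window is sized
to contain exactly `n_steps` heel strikes with margins at both edges.

Noise is isotropic per-landmark Gaussian in pixels plus Bernoulli dropout,
seeded through one generator — identical config + seed is bit-identical.
The emulated MEMS reference stream is truth resampled to the sensor rate
plus Gaussian angular noise.

**What passing does not show.** The simulator has no perspective, no
occlusion, no correlated pose-estimator failure modes (e.g. low
clothing/background contrast, which degrades real step counting), no soft
tissue or clothing motion, and a stylized joint trajectory. Passing
recovery tests demonstrates the pipeline's correctness and noise
robustness, not field accuracy of a specific camera + network stack.

## Problem sizes and runtime

Tests and the acceptance script run simulations of 30/60/90 steps
(≈1 200–3 600 frames), 10-seed noise studies at 30 steps, and 100-seed
static-capture bias studies at 50 frames each; the full suite completes in
well under a minute on one CPU, chosen so the distribution-level claims
(median count error, bias < 0.5%) are stable across seeds at desk scale.

## Known limitations

- Planar kinematics only; depth is carried but unused.
- One scale for the whole capture: a marker moving toward/away from the
  camera between observations inflates the reported dispersion rather than
  being corrected.
- The static-capture gate rejects slow drift (> 2 px/frame median) but not
  a subject swaying symmetrically about the mean pose.
- Running, stairs and pathological gait are out of scope; the state machine
  assumes the canonical six-phase cycle.
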