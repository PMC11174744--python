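# gaitpix

Markerless optical gait analysis from 2D pose-landmark time series.

`gaitpix` is a library + CLI for researchers who capture human walking with
an ordinary camera and a whole-body pose estimator, and who need validated
gait quantities out the other end: knee/ankle joint angles, anthropometric
segment lengths, the six canonical gait phases, step counts, step length and
traveled distance — together with the error statistics used to validate such
systems against tape measures, manual counts and MEMS-IMU references.

The package does not run a camera or a pose network. It consumes their
output — per-frame named 2D keypoints with visibility scores, and the pixel
corners of a square fiducial (ArUco-style) marker of known physical size —
as plain CSV, and ships a sagittal-plane gait simulator that generates those
same streams with full ground truth, so the whole pipeline is testable
without hardware.

## Method

**Metric scale.** A square marker of side $s$ cm observed with pixel corners
$c_1..c_4$ gives a scale $\rho = s / \bar{e}$ cm/px, where $\bar{e}$ is the
mean of the four edge lengths; the median of $\rho$ over observations is
used. All lengths are pixel distances times $\rho$.

**Joint angles.** For landmarks $a, b, c$ the interior angle at $b$ is

$$\theta = \arccos\frac{(a-b)\cdot(c-b)}{\lVert a-b\rVert\,\lVert c-b\rVert} \in [0^\circ, 180^\circ],$$

with 180° = full extension. Knee: $\theta$(hip, knee, ankle); ankle:
$\theta$(knee, ankle, toe). Angles are computed in the image plane
(sagittal-plane assumption) and optionally smoothed with a centered moving
average.

**Gait phases.** Heel and toe contact are detected against an estimated
ground line (a high quantile of heel height) with hysteresis thresholds
normalized by leg length. Contact transitions and ankle-crossing geometry
drive a sequential-flag state machine over the cycle

heel strike → foot flat → midstance → heel off → initial swing → mid swing,

where each phase fires only if the previous phase was the last one emitted
for that side — preventing skipped or double-counted steps. Steps are
validated heel strikes; step length is the horizontal mid-foot to mid-foot
distance at foot-flat; traveled distance is steps × mean step length
(treadmill) or the cumulative sum (overground).

**Validation statistics.** Absolute error $|m - r|$, relative error
$|m - r| / r \times 100\%$ (with the denominator convention — ground truth
vs reference instrument — recorded explicitly), and RMSE between angle
streams after linear resampling onto a common timebase.

## Worked example

Simulate a 30-step treadmill walk at 25 fps (44 cm steps, cadence
38 steps/min, ~1.0 km/h) and analyze it:

```bash
cat > walk.yaml <<EOF
n_steps: 30
seed: 1
EOF
gaitpix simulate -c walk.yaml -o capture
gaitpix analyze -l capture/landmarks.csv -m capture/marker.csv -o analysis
```

which prints

```
steps: 30  mean step length: 44.00 cm  distance: 13.20 m
```

All 30 planted steps are recovered, the step length matches the configured
44 cm, and the distance is steps × mean step length = 30 × 0.44 m. The
output directory holds `angles.csv` (raw and smoothed knee/ankle series),
`events.csv` (one row per phase event) and `summary.csv`:

```
step_count,mean_step_length_cm,traveled_distance_m,complete_cycles
30,44.0,13.2,29
```

The same `analyze` command on a static capture (`gaitpix simulate --static`)
produces `profile.csv` with the four anthropometric measurements
(knee–heel, hip–ankle, ankle–toe, height) instead of gait events.

Error tables against a reference are produced with
`gaitpix evaluate --measured m.csv --reference r.csv` (label/value CSVs), or
`--kind series` for angle-stream RMSE.

As a library:

```python
from gaitpix import (SimulationConfig, simulate_gait, detect_gait_phases,
                     count_steps, scale_from_marker)

seq, markers, truth = simulate_gait(SimulationConfig(n_steps=30, noise_sigma_px=2.0))
events = detect_gait_phases(seq)
assert abs(count_steps(events) - truth.step_count) <= 1
```

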