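# yawkit

Heading-based activity metrics from animal-borne tri-axial accelerometer +
magnetometer loggers.

Accelerometers alone cannot resolve rotation about the yaw axis, which for
slow-moving animals (sea turtles being the canonical case) often carries more
behavioural signal than dynamic acceleration does. `yawkit` implements the
full derivation chain from raw logger output to yaw-rotation activity
metrics:

1. **Calibration** — hard/soft-iron correction of the magnetometer by
   algebraic least-squares ellipsoid fitting of an "m-sphere" calibration
   rotation.
2. **Orientation** — static (gravity) acceleration via a centred 2 s running
   mean; pitch β = atan2(Sₓ, √(S_y² + S_z²)) and roll analogously, both in
   [−90°, +90°]; tilt compensation of the calibrated mag vector; compass
   heading H = mod(360 + atan2(−m_y, m_x)·180/π, 360), North 0°, East 90°.
3. **Rotation metrics** — VeDBA = √(x² + y² + z²) of the dynamic acceleration
   components; angular velocities about pitch/roll/yaw (AVeP, AVeR, AVeY) as
   finite differences of the 2 s-presmoothed angles after subsampling to
   1 Hz, with yaw differences wrap-corrected into [−180°, +180°]; AVeY also
   at 5 s and 10 s steps (°/5s, °/10s); AAV = √(AVeP² + AVeR² + AVeY²).
4. **Turn analysis** — conditional running cumulative sums of AVeY emitting a
   turn event each time a threshold angle (20/45/90/180°) is totalled in
   either direction, expressed as signed percentage coverage; and cumulative
   heading (**CuHe**), the percentage of the 360° yaw circle visited since
   the last complete revolution.
5. **Dive segmentation** — flat U-dives (≥ 3 m, depth-stable bottom phase),
   bottom-phase per-dive means, and association statistics: Spearman rank
   correlations plus a linear mixed model of per-dive mean VeDBA on mean
   |AVeY| with per-animal random intercepts and slopes.
6. **Simulator** — synthetic deployments (behaviour-dependent heading
   dynamics, trapezoidal dives, iron distortion, sensor noise) with known
   ground truth, so every stage is verifiable by recovery rather than by eye.

Intended users: movement ecologists processing daily-diary-style logger data
(40 Hz acc in g, mag in Gauss, pressure-derived depth) and methods developers
who need a ground-truthed IMU test bench.

## Worked example

```python
import numpy as np
import yawkit as yk

# synthetic deployment: a turtle circling at 6 deg/s during an 8 m dive
spec = yk.DistortionSpec(hard_iron=[0.10, -0.05, 0.20],
                         soft_iron=np.diag([1.2, 0.9, 1.1]))
plan = [{"behavior": "quiescent", "duration_s": 30, "jitter_sd": 0.2},
        {"behavior": "circling", "duration_s": 180, "rate_dps": 6.0,
         "dive_depth": 8.0},
        {"behavior": "quiescent", "duration_s": 30, "jitter_sd": 0.2}]
truth = yk.simulate_trajectory(plan, rate_hz=40.0, seed=1)
raw = yk.synthesize_imu(truth, spec, seed=2)

# calibrate from a separate rotation segment, then derive everything
cal = yk.generate_calibration_rotation(spec, 1000, seed=3)
fit = yk.fit_ellipsoid(cal.mag)
print("hard-iron offset:", np.round(fit.offset, 4))

metrics = yk.compute_metrics(raw, fit=fit)          # 1 Hz after subsampling
circling = truth.behavior[::40][:len(metrics)] == "circling"
print("mean AVeY while circling: %.2f deg/s" % np.nanmean(metrics.avey_1[circling]))
print("mean VeDBA: %.3f g" % np.nanmean(metrics.vedba))

cov = yk.turn_coverage(metrics.t, metrics.avey_1, threshold=45.0)
ch = yk.cuhe(metrics.t, metrics.heading)
print("45-degree turns:", cov.n_events, "| full revolutions:", ch.total_revolutions)
```

prints

```
hard-iron offset: [ 0.1    -0.0499  0.1999]
mean AVeY while circling: 5.97 deg/s
mean VeDBA: 0.043 g
45-degree turns: 23 | full revolutions: 3
```

The fitted offset recovers the injected hard-iron bias, the derived yaw rate
matches the 6 °/s truth within smoothing bias, VeDBA sits in the sub-0.08 g
regime typical of slow swimmers, and the 1080° of circling shows up as 23
completed 45° turn events (the last accumulation is still in progress at the
record's end) and three complete revolutions of cumulative heading.

A `yawkit` console script exposes each stage
(`simulate`, `convert`, `calibrate`, `derive`, `metrics`, `turns`, `dives`,
`stats`) and a `run` command driving the whole pipeline from a YAML config;
see `yawkit --help`.

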