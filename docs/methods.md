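# Methods

This note documents the models, conventions and numerical choices behind
`yawkit`, and what the synthetic test bench does and does not establish about
real deployments.

## Sensor model and frames

The body frame is x surge (anterior), y sway, z heave (dorsal); a level,
motionless tag reads static acceleration (0, 0, 1) g. The world frame is
x North, y East, z up. Attitude is parameterised as yaw ψ (heading, degrees
clockwise from magnetic North), then pitch β (positive nose-up, rotation
about sway), then roll φ (rotation about surge); the body→world matrix is
Rz(ψ)·Ry(−β)·Rx(φ) (with Rz oriented so increasing ψ turns North→East). The
gravity reaction vector in the body frame is therefore
(sin β, cos β sin φ, cos β cos φ), which is what the pitch/roll formulas
invert, and the magnetometer reads the ambient field rotated by the transpose
of the attitude matrix, subject to iron distortion.

Heading is magnetic: no declination correction is applied (a constant offset
in any case, irrelevant to every differential metric here).

## Orientation chain

* **Static acceleration** — centred running mean per channel. The window is
  2h+1 samples with h = round(window·rate/2) (2 s default, so h = 40 at
  40 Hz), truncated *symmetrically* at the record edges so no phase shift is
  introduced. Non-finite samples are excluded from each window's mean rather
  than propagated; entirely empty windows yield NaN.
* **Pitch/roll** — atan2(Sₓ, √(S_y²+S_z²)) and atan2(S_y, √(Sₓ²+S_z²)),
  degrees. Both are bounded in [−90°, +90°] by construction because the
  second atan2 argument is non-negative. A (near-)zero static vector marks
  the sample invalid; nothing is interpolated.
* **Tilt compensation** — the calibrated mag vector is de-rotated by roll
  about surge, then by pitch about sway. With the square-root-form roll
  above, this inversion is exact when either angle is small or the other is
  zero; when pitch and roll are simultaneously large the sqrt-form roll
  differs from the Euler roll and heading degrades smoothly. This is the
  operating regime of carapace tags on slow swimmers, and mirrors the known
  breakdown of pitch/roll derivation near ±90°.
* **Heading** — H = mod(360 + atan2(−m_y, m_x)·180/π, 360). Samples with a
  negligible horizontal field component (|(m_x, m_y)| < 1e-6·|m|; field
  parallel to the body vertical) are flagged invalid.
* **Circular statistics** — means and rolling smooths of heading are taken
  on the unit circle via trigonometric moments and returned in [0, 360).
  A mean resultant length below 1e-12 (antipodal cancellation) is reported
  as undefined (NaN). Pitch and roll are smoothed linearly: bounded in ±90°,
  they cannot wrap.

## Magnetometer calibration

Hard iron adds a constant bias; soft iron applies a linear map; together
they turn the calibration sphere into an off-centre ellipsoid. The fit is
the algebraic least-squares quadric fit (linear in the 9 coefficients of
x'Mx + 2b'x = 1, solved by `lstsq` on a cloud pre-scaled for conditioning).
The centre is −M⁻¹b; the correction matrix is the unique symmetric
positive-definite square root of the recentred form, normalised to
determinant 1 so the split between shape and overall radius is canonical.
The symmetric (rotation-free) choice is deliberate: heading only needs
sphericity, and the global rotation of the fit is unobservable from the
cloud alone. Applying the calibration maps each reading to
shape·(m − offset)/mean_radius, nominally on the unit sphere; the RMS
deviation of the corrected norms from 1 is reported as `rms_residual`, with
no hard acceptance threshold — what residual is tolerable depends on the
deployment and is left to the user.

At least 9 points in general position are required; coplanar or collinear
clouds, and quadrics that are not ellipsoids, raise a degenerate-geometry
error rather than returning a misleading fit.

## Rotation metrics

The pipeline order is fixed: presmooth the angles with the 2 s window at the
native rate (circular for yaw, linear for pitch/roll), subsample to 1 Hz by
plain selection of every 40th sample (no averaging), then difference.
Angular velocities are raw finite differences x_i − x_{i−step}; yaw
differences are wrap-corrected by adding 360 when below −180 and subtracting
360 when above 180 (strict inequalities, so an exact ±180 half-revolution
keeps its sign — both signs encode the same rotation). Multi-scale AVeY
(steps of 5 and 10 samples) stays in natural units of °/5s and °/10s, not
per-second rescalings. The first `step` outputs are undefined (NaN), not
zero-filled. AAV is the per-sample norm of (AVeP, AVeR, AVeY) and is
therefore ≥ each component magnitude. An optional post-differentiation
linear smooth of AVeY is exposed (off by default) for display parity with
windowed presentations.

VeDBA subtracts the 2 s running mean per acceleration channel and takes the
norm of the residual; it is computed at the native rate and subsampled
alongside the angles.

## Turn counters and CuHe

Turn coverage is a signed conditional cumulative sum of AVeY: opposite-
direction rotation decrements the accumulator, and each time its magnitude
reaches the threshold (20/45/90/180° defaults) an event of that sign is
emitted. On reset the overshoot remainder is carried by default
(`reset="remainder"`), which makes event totals independent of sample phase
and exact for constant rates; a `reset="full"` switch zeroes instead. A
single large step can emit several events. Non-finite AVeY samples
contribute nothing.

CuHe partitions the circle into 1° bins (any divisor of 360 is allowed) and
marks every bin touched by the shorter wrap-corrected arc between
consecutive valid samples, so fast turning cannot alias past orientations.
Coverage percent is monotone between resets; at 100% the revolution counter
increments, the set clears and the current bin is immediately re-marked (so
percent is never 0 while data exist). An alternative entry point integrates
wrap-corrected AVeY from a starting heading and is tested to be equivalent
wherever per-step rotation stays within ±180°; the direct-heading path is
the default because it cannot accumulate drift.

## Dive segmentation

A dive is a maximal run of depth > 0.5 m (surface threshold ≈ pressure
noise floor); retained iff max depth ≥ 3 m. The bottom phase spans the first
to last sample at ≥ 80% of max depth. Flat-U classification requires bottom
duration ≥ 30 s and bottom-depth s.d. / max depth ≤ 0.1. The 80% fraction,
0.1 flatness and 30 s dwell are this package's operationalisation of the
"flat U-shaped (type 1a)" profile — dive-shape taxonomies in the literature
are verbal — and all three are config keys. Per-dive summaries use
arithmetic means of VeDBA and of |AVeY| (signed yaw means cancel by
symmetry and would be uninformative), the circular mean of heading, turn
events per minute within the bottom phase, and CuHe revolutions within the
phase. Dives with an empty bottom phase are dropped with a log entry.

## Association statistics

The mixed model regresses per-dive mean VeDBA on per-dive mean |AVeY| with
per-animal random intercepts and slopes, via statsmodels `MixedLM`.
Estimates and standard errors come from the REML fit; the likelihood-ratio
test for the fixed slope compares ML fits of the model with and without the
fixed slope (same random structure), referred to χ²(1). A singular
random-slope fit falls back to random intercepts with a warning. Variance
explained follows the Nakagawa decomposition: marginal R² =
var(fixed)/(var(fixed)+var(random)+var(resid)) with the random-effect
contribution averaged over the design; conditional R² adds the random part;
ICC is the intercept-variance share σ²_u0/(σ²_u0+σ²_ε). No outliers are
removed by default — residual-based removal is subjective — but an optional
studentized-residual cutoff flag is provided. The model itself is
deliberately off-the-shelf; an independent cross-check against R/lme4 on a
small fixture is part of the test suite.

## Simulator

The simulator is the package's ground truth. Behaviours map to yaw
dynamics: `quiescent` (constant heading + white jitter, 0.5° s.d. default),
`circling` (constant signed rate, 6 °/s default), `oscillatory-search`
(sinusoid, 45° amplitude, 20 s period, 0.2 °/s centre drift) and `transit`
(smoothed random-walk wander, 2° scale). Dives are trapezoidal (0.25 m/s
descent/ascent, ±25° pitch during the vertical phases, level bottom).
Sensor rendering inverts the orientation chain exactly: body-frame gravity
plus a 0.5 Hz, 0.05 g flipper-beat sinusoid (keeping VeDBA in the sub-
0.08 g regime reported for slow swimmers) and white accelerometer noise
(0.02 g); ambient field 0.35 G at 40° inclination (mid-latitude-like; the
heading math is magnitude-invariant after normalisation), soft-iron matrix
and hard-iron bias applied, white mag noise 2 mG (the loggers' LSB scale);
depth noise 0.02 m. Calibration segments lay field directions on a
seed-rotated Fibonacci lattice so the distorted cloud traces the full
ellipsoid.

Noiseless, the full chain recovers heading to ~1e-13° (level or pitch-only
postures) and iron parameters to 1e-9; with the realistic noise defaults,
heading RMSE is ≈0.5°, comfortably inside the 1–2° precision expected of
tilt-compensated compasses. What the simulator does *not* emulate: axis
misalignment between the two sensors, temperature drift, centripetal
contamination of the static vector during rapid cornering, magnetic anomaly
gradients, and behaviour-dependent flipper kinematics. Passing ground-truth
recovery therefore validates the arithmetic of the chain, not the field
accuracy of any particular deployment.

The two-level per-dive generator used for statistical validation draws, per
animal, a random intercept (s.d. 0.015 g) and random slope (s.d. 0.0002)
about a population line with intercept 0.04 g and slope 0.0029 g per °/s,
residual s.d. 0.012 g, and per-dive mean |AVeY| uniform on 0–20 °/s — values
chosen to emulate the reported regime for slow swimmers (per-dive VeDBA
means below ~0.08 g, a milli-g-scale VeDBA–AVeY slope, modest between-animal
heterogeneity). Validation fits 200 fleets of 5 animals × 100 dives for ±2
SE slope coverage and 200 zero-slope fleets for the LRT's empirical type-I
error; those sizes keep the whole statistical check under a minute on one
CPU while leaving binomial noise (s.d. ≈1.5 percentage points at the 5%
level) small relative to the acceptance bands.

## Numerical conventions and degenerate inputs

* All angles in degrees externally; radians only inside trig calls.
* Heading outputs always in [0, 360); 360 itself never occurs (mod).
* Invalid samples (zero static vector, vertical field, NaN inputs) are
  flagged and propagated as NaN, never interpolated.
* Even-length smoothing windows are rounded to the nearest odd sample count
  (2h+1), matching the symmetric-window definition.
* Turn-event ties at exactly the threshold fire the event (≥, not >).
* CSV output uses %.12g so round-trips preserve 9+ significant digits; NaN
  cells are written literally as "NaN".
* Pipeline outputs contain no wall-clock content, so identical configs and
  seeds reproduce byte-identical files.

## Known limitations

* The tilt correction inherits the sqrt-form roll's approximation under
  simultaneous large pitch and roll (see above).
* Dive-phase thresholds are heuristics; deployments with gradual descents
  or sloping bottoms may need the config keys adjusted.
* The LRT's χ²(1) reference is asymptotic in the number of animals; with
  very few groups it runs slightly conservative-to-liberal depending on the
  random-effect structure (the type-I simulation in the test suite bounds
  this empirically).
* No gyroscope fusion, no dead-reckoning track reconstruction, no automatic
  behaviour labelling — the metrics here are inputs to such analyses, not
  replacements for them.
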