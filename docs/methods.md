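# Methods

`mmtrack` simulates and reconstructs the passage of a single permanently
magnetized microsphere through a tube phantom, monitored remotely by an
array of magnetometers (SQUID-class sensitivity). This note documents the
models, the estimators, the defaults, and what the synthetic conditions do
and do not establish about real measurements.

## Physical model

### Flow and sphere kinematics

The carrier flow is laminar Poiseuille flow in a tube of inner diameter
`d_tube`: the axial fluid velocity at relative radius `rho = r/R` is
`v(rho) = v0 (1 - rho^2)`, with centerline velocity `v0` equal to twice the
mean velocity `Q / (pi R^2)`. The default operating point is a flow rate of
30 ml/min in a 1.5 mm tube of kinematic viscosity 2 mm^2/s, i.e. a mean
velocity of 0.28 m/s, a centerline velocity of 0.57 m/s (the nominal set
point is quoted as 0.56 m/s), and Reynolds number 212 — laminar but
intermediate, so the parabolic profile is a good working assumption.

A freely suspended rigid sphere in shear translates with the local fluid and
rotates at half the local vorticity. On the streamline at relative radius
`rho` this gives

    sphere speed        v     = lag * v0_local * (1 - rho^2)
    rotation frequency  f_rot = v0_local * rho / (2 pi R_local)

A constriction that reduces the local diameter to `d_local` raises the local
centerline velocity by mass continuity, `v0_local = v0 (d_tube/d_local)^2`,
and halves the radius in proportion; a 50% diameter reduction therefore
multiplies the speed by 4 and the rotation frequency by 8. Eliminating `rho`
in the unconstricted tube at `lag = 1` yields the closed-form
velocity-frequency relation of quadratic flow,

    v = v0 - (pi f_rot d_tube)^2 / v0 ,

which the simulator satisfies to 1e-9 relative (it is used as a closure test,
not as an implementation shortcut).

The `lag` factor is a single scalar multiplying the translational speed only.
Dense spheres (the ~7x-denser-than-carrier NdFeB tracers) systematically lag
the undisturbed flow; the default for the large-sphere configuration is 0.65.
No force balance (Stokes drag transients, lift, wall interactions) is
attempted: the lag is an empirical, constant slip factor, and rotation is
assumed unlagged (pure shear-driven rolling).

### Phantom geometry

The centerline runs along x through a straight section of configurable
length, then turns through a circular bend (default radius 2 cm, angle 90°)
in the horizontal plane; positions are parameterized by arc length. The
constriction is a span of `constriction_length` (default 1 cm) at reduced
diameter `d_tube (1 - reduction)`, joined to the full bore by cosine tapers
of `taper_length` (default 1 mm) at each end. The taper shape is a modeling
choice — only the constricted span and the reduction degree are physically
specified; any smooth monotone ramp of millimeter scale gives
indistinguishable tracks at 750 Hz.

Inside the bend, secondary (Dean-type) circulation transports particles
across streamlines toward the tube center. This is represented
phenomenologically: the relative radius decays exponentially at
`bend_drift_rate` (default 5 1/s) while the sphere is in the bend. The rate
is not derived from a Dean-flow solution — the observable consequence
(velocity up, rotation frequency down) is directional, and the classifier
only uses the direction.

The sphere's rotation axis is the local vorticity direction, perpendicular
to the flow tangent and to the radial offset. The default initial offset is
half the radius toward the bottom wall (gravity, given the density
mismatch), which puts the moment rotating in the vertical plane containing
the flow. Optional kinematic lateral oscillations (a radial displacement
locked to a harmonic of the rotation phase) can be superimposed to emulate
the oscillatory traces seen in practice; they are off by default because
their physical origin is unsettled and the imposed form is purely
descriptive.

### Magnetic forward model

The sphere is a point dipole. A channel at `r` with unit normal `n` measures

    B = (mu0/4pi) [ 3 (n.u)(u.m) - (n.m) ] / |r - r'|^3 ,   u = (r-r')/|r-r'|

with the moment direction parameterized by polar angle `theta` and azimuth
`phi`, so a source of known moment magnitude has five degrees of freedom.
`mu0/4pi` is taken as exactly 1e-7 T m/A. Sensors are points (no pickup-coil
area integration, no crosstalk, no drift).

The default array is a planar 7x7 grid of triaxial stations (147 channels)
covering 15 cm x 20 cm at 3.5 cm above the tube. The reference instrument
is a 304-SQUID, four-layer vector magnetometer system of which 133 channels
were used; its exact channel layout is not public, so the planar triaxial
grid is an acknowledged functional stand-in with a comparable channel count,
vector sensitivity, and source-sensor distance. Channel noise is white
Gaussian with density 3 fT/sqrt(Hz) (no 1/f term), giving a per-sample sigma
of `3 fT * sqrt(750/2) = 58.1 fT` at the default 750 Hz sampling, and a
~400 fT expected peak-to-peak excursion over a one-second record. One
integer seed fully determines the noise matrix and is stored in the
recording metadata.

## Inverse problem

Each sample is fit independently by minimizing the squared misfit between
the measured channel vector and the dipole model over (position, theta, phi)
with the moment magnitude held at its known value — damped least squares of
the Levenberg-Marquardt family, implemented with a trust-region reflective
solver so that box constraints on the position are handled natively.
Residuals are scaled to femtotesla and positions to millimeters inside the
solver for conditioning.

Tracking warm-starts each sample at the previous fitted pose and confines
the position to a box of half-width `v_max / f_s` per coordinate (2.67 mm at
the defaults `v_max = 2 m/s`, `f_s = 750 Hz`) — the maximum physically
plausible per-sample displacement. The box makes the per-axis step bound an
invariant of every track, not a post-hoc filter.

Cold starts (the first sample, or any isolated fit) use a multi-start sweep:
a coarse position grid (default 5 mm spacing over the array footprint,
depths 1-6 cm below the sensor plane) scored analytically against 26 moment
directions (cube faces, edges, corners) using the linearity of the field in
the moment; the best few candidates are refined by full fits and the lowest
refined residual wins, with ties broken by grid order for determinism.

Angles are optimized unconstrained and folded back into `theta in [0, pi]`,
`phi in [0, 2 pi)` afterwards (folding theta compensates phi by pi), which
avoids boundary sticking at the poles. Non-convergence is reported in the
per-sample diagnostics, never raised. The reduced chi-square normalizes the
residual by the channel noise variance and `P - 5` degrees of freedom; a fit
with reduced chi-square below 1.5 whose fitted field peak is under 3 channel
sigmas is flagged `low_signal` (the model is consistent with noise).

## Kinematic estimators

**Velocity.** `v_i = |r'_i - r'_{i-1}| f_s`, assigned to the later sample,
then a centered moving average of 10 samples (the window shrinks at the
edges). The step-index convention is immaterial beyond the edges once
smoothed. Note the norm of a noisy displacement is biased upward; at the
default large-sphere SNR the bias is a few percent.

**Rotational frequency.** Estimation runs on the moment-direction
*components* (cos theta, sin theta cos phi, ...) rather than the raw angles,
which wrap. Two steps:

1. A prefit frequency trace `f_pre`: the dominant non-DC bin of the
   spectrogram of the component traces, refined by the wrapped phase rate —
   the angle swept between consecutive moment directions times `f_s / 2 pi`,
   median-filtered. The phase rate follows rapid chirps (a constriction
   transit lasts only ~5-15 samples at the defaults) that a spectrogram
   segment averages away; the spectrogram provides the global sanity check
   and the no-rotation decision.
2. Sliding-window sine fits: window width `W = 2 f_s / f_pre` samples (two
   expected periods, floor 6 samples), sized by the fastest prefit frequency
   within the local lookahead so that short bursts get windows matched to
   their own scale; each window gets a four-parameter sine fit (amplitude,
   frequency, phase, offset) seeded at the local `f_pre`, applied to the
   component with the most variance in that window; fits with relative
   residual above 0.8 fall back to the prefit value. Window-center estimates
   are linearly interpolated to all samples.

A non-rotating sphere (component standard deviations below 1e-3) returns an
all-zero trace with a `no_rotation` flag rather than an error. Rotation
faster than the Nyquist frequency (375 Hz at default sampling — reached
inside a 50% constriction) aliases, as it must for any sampled estimator;
the aliased frequency still rises far above baseline, so event detection is
unaffected, but the absolute frequency inside such a burst is not
quantitative. The diameter-reduction estimate therefore uses velocity, not
frequency.

**Event classification.** Windowed means (default window 50 ms, hop half a
window) of the velocity and frequency traces are compared to the track
baseline (median windowed value) as relative changes. Both up beyond
`rel_threshold` (default 0.15) marks a *constriction*; velocity up with
frequency down a *shift_to_center*; the mirror pattern a *shift_to_wall*;
otherwise *steady*. Adjacent same-kind windows merge into one event with its
extent read off the x trace. A constriction is only confirmed if both traces
return to baseline later in the track — a monotone rise instead indicates a
progressively narrowing vessel and is deliberately not reported as a local
stenosis. The thresholds are exposed, not inferred: the directional logic is
physically fixed, the magnitudes are operating-point choices (0.15 detects a
17% reduction, whose velocity factor is 1.45, while leaving straight-tube
noise below threshold at the default SNR).

The reduction degree of a constriction event is recovered from mass
continuity, `reduction = 1 - sqrt(v_baseline / v_peak)`. Because a transit
can be shorter than both the classifier window and the 10-sample velocity
smoother, windowed or smoothed means dilute the peak; the estimate therefore
uses the unsmoothed per-sample velocity (median-filtered over 3 samples for
spike robustness) inside the event interval. With the default geometry this
recovers 50% and 33% reductions within ~0.01 absolute at the large-sphere
SNR.

## Problem sizes and numerical defaults

Default runs simulate 0.3-1.0 s of passage (about 200-750 samples at
750 Hz) over a 147-channel array; a full pipeline (simulate, synthesize,
track, analyze) completes in seconds on one CPU, and the bundled end-to-end
checks use 0.33 s segments around the constriction. Optimizer tolerances
default to 1e-12 (cost/step) and 1e-10 (gradient); the multi-start refine
count is 3. Degenerate inputs are handled explicitly: empty recordings,
non-finite samples, spheres larger than the constricted lumen, and sensors
coincident with the source all raise typed errors, while non-convergence
and low signal are per-sample flags.

## What the synthetic conditions do not show

The generator emulates the kinematics and the measurement chain, not the
fluid dynamics: no Navier-Stokes or Dean-flow solution, no lift or wall
forces, no sphere-chain dynamics, no blood rheology, and imposed (not
emergent) lateral oscillations. Sensor imperfections (calibration error,
gradiometric residuals, 1/f noise, environmental interference such as
cardiac fields) are absent. Passing tests therefore establish that the
reconstruction and classification chain is correct and meets its accuracy
targets *under the stated noise and kinematic model*; they do not by
themselves validate the flow model against a physical phantom.
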