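# Methods

This note documents the models and numerical choices behind `gaitstab`: what
each stage computes, the assumptions it makes, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Scope and data model

The pipeline analyzes one walking trial at a time from two streams: a
kinematic recording (3-D positions of the whole-body centre of mass (CoM),
heels, first/fifth metatarsals, sacrum, hip centres and C7 at 120 Hz, plus
the mediolateral trunk angular velocity in deg/s) and a per-foot insole
recording (vertical ground reaction force and mediolateral centre of
pressure at 100 Hz).  A stride runs from one right heel strike to the next;
each stride carries an optional ground-condition tag (S = summer, W1 =
cleared winter ground, W2 = snow/ice) that flows through to the statistics.

## Events and synchronization

Insole heel strikes are threshold crossings of the vertical force (30 N
default, the conventional contact cut-off for instrumented insoles), with a
0.2 s unloaded refractory interval that rejects chatter around the
threshold and is shorter than any plausible swing phase.  Kinematic events
use a contact-height scheme: a foot marker within 2 mm of its floor level
counts as in contact; the entry transition is the heel strike (guarded by
the heel's horizontal speed having dropped from its swing peak within
±50 ms), the exit transition of the toe marker with sustained upward
velocity afterwards is the toe off.  We chose threshold detection over
extremum-based detection because it is deterministic at sample resolution,
which makes downstream results reproducible bit-for-bit; on the synthetic
data it recovers every event at its exact sample.

The two streams run on independent clocks.  Subjects jump three times at
the start of a trial; during flight the insoles unload while the CoM is in
free fall.  Both streams are reduced to binary flight masks (force < 30 N;
|vertical CoM acceleration + g| < 3 m/s²) over the first 30 s, and the
constant clock offset is the centre of the cross-correlation plateau of the
masks.  Rectangular masks of equal width correlate to a plateau rather than
a peak; taking its centre removes the half-width bias, leaving the estimate
within half an insole sample.  A single constant offset is applied; linear
clock drift is not modelled.

Recordings sampled above 120 Hz are decimated by polyphase resampling with
a zero-phase anti-alias filter, so event times are not biased by filter
delay.

## Stride frames and normalization

Each stride gets its own coordinate frame: origin at the right heel at the
opening heel strike, z global up, x the horizontal unit vector along the
net sacrum displacement over the stride (anterior–posterior regardless of
heading, so turns are absorbed stride-by-stride), y = z × x (mediolateral,
leftward positive).  Channels are resampled to a 101-point percent-gait
grid (0–100 %, the conventional grid) with shape-preserving PCHIP
interpolation; boundary samples are preserved exactly.  CoM velocity and
acceleration are central differences on the uniformly sampled 120 Hz data
*before* any time normalization — differentiating percent-gait arrays would
conflate time warping with dynamics.  Note that PCHIP's monotonicity
limiter is not exactly rotation-equivariant: resampling and the rigid frame
transform commute to interpolation accuracy (≲0.1 mm here), not to machine
precision.

Leg length L is computed per stride as the mean distance from the stance
(right) fifth-metatarsal marker to the CoM over that foot's stance phase,
the inverted-pendulum length used both for the extrapolated CoM and for
nondimensionalization.

## Margins of stability

The extrapolated centre of mass is XCoM = CoM + sqrt(L/g) · CoM velocity,
per horizontal component.  At each heel strike the forward margin
(FW MoS) is the AP distance from the XCoM to the heel marker of the
anterior foot and the backward margin (BW MoS) the AP distance from the
posterior foot's fifth-metatarsal marker to the XCoM; their sum equals the
AP extent of the base of support, an identity the tests assert per event.
The anterior foot is resolved by comparing heel positions rather than
assuming the striking foot leads, which is robust to atypical strides.  In
steady walking the XCoM at contact is typically ahead of the leading heel,
so FW MoS is negative; larger (less negative) values mean more resistance
to a forward loss of stability.  The mediolateral margin is the minimum,
over the single-support phase, of the signed ML distance from the XCoM to
the stance-foot fifth-metatarsal marker, positive when the XCoM is medial
to the marker (signed, not absolute, so lateral excursions show up as
negative margins).

## Local divergence exponent

Whole-body dynamic stability is summarized by a Rosenstein-style local
divergence exponent on one CoM-velocity component at a time.  Strides are
resampled to 100 samples each and concatenated, so one time unit is one
stride; the series is delay-embedded with dimension 5 and delay 10; each
embedded point is paired with its nearest neighbour outside a Theiler
window of one stride (excluding trivially adjacent neighbours); and the
mean log Euclidean separation of the pairs is tracked forward.  The
exponent is the least-squares slope of that divergence curve over its first
half stride — the conventional short-term window — expressed per stride.
The per-stride sample count, fit window and Theiler width are all
configurable because different implementations in the literature differ in
exactly these choices.  Distances are floored at 1e-12 before the log so a
perfectly periodic signal yields a flat curve (slope ~0) rather than
log(0).  Comparisons should always use the same number of strides per
subject; the pipeline clips to the configured count for exactly that
reason.

## Stepping and compensation regressions

The stepping regression models each foot placement as linear feedback on
the CoM state at the midstance of the preceding single-support phase:

    dFP = b1 dx + b2 dy + b3 dz + b4 dx' + b5 dy' + b6 dz' + b7 dx'' + b8 dy'' + b9 dz''

fitted per subject by OLS without intercept, once for the AP and once for
the ML placement coordinate.  The R² measures adherence to the stepping
strategy; the gains measure how strongly placement reacts to state
deviations.  Design choices, each exposed as configuration:

- **Midstance** is the temporal midpoint of the single-support window
  (50 % by default), a common operationalization.
- **Both left and right placements** enter the fit (doubling the sample);
  mediolateral quantities of left-foot placements are negated before
  pooling (mirror symmetry).
- **Deviations are taken from the per-side mean.**  The pooled series mixes
  two step types whose baseline values differ (for example the AP distance
  from the stride-opening heel strike to the two midstances differs by half
  a stride); centring within side removes these offsets so that gait
  asymmetry never masquerades as control gain.
- **Foot placement is measured relative to the CoM position at the
  heel-strike instant** (in stride-frame axes), as in the foot-placement
  control literature, rather than relative to the stride origin.  The
  origin is the *previous* right heel position, so an origin-anchored
  response would contain the previous placement's deviation — an
  autocorrelated response that biases gain recovery.  The CoM position
  entering the *predictor* is likewise anchored at the CoM position at the
  stride-opening heel strike, which removes forward progression without
  tying the predictor to any foot marker.

The stepping error of a placement is predicted minus actual ML placement
(the OLS residual with its sign flipped).  The compensation regression
relates this error to the ankle and trunk strategies:

    Error = b_ankle * dCoP_mean + b_trunk * dOmega_trunk_mean

where dCoP_mean is the stance-phase mean ML centre of pressure of the
stance foot serving the placement and dOmega_trunk_mean the mean ML trunk
angular velocity over the single-support window preceding the placement
(deg/s).  With two placements per stride a per-stride averaging window
cannot be paired one-to-one with placements, so both windows are per-step;
a whole-stride trunk window remains available as configuration.  The fit
is two-predictor OLS without intercept on mean-centred data and reports
per-coefficient t-tests against zero.

## Spatiotemporal measures

Per stride: stride time (successive right heel strikes), stance time
(right heel strike to right toe off), speed (mean AP CoM velocity), stride
length (AP distance between the right heel positions opening and closing
the stride) and step width (ML distance between right and left heel
markers at their respective heel strikes, reported as a magnitude so
widths are positive).  Per subject: mean and RMS variability, where
variability is the sample (n−1) standard deviation.

## Nondimensionalization and statistics

Before group comparisons all measures are scaled by inverted-pendulum
factors: lengths by L, velocities by sqrt(gL), accelerations by g, times
by sqrt(L/g), with g = 9.806 m/s².  Two-group (summer vs winter) contrasts
use two-sided unpaired t-tests, pooled-variance by default with Welch as an
option.  Three-condition contrasts (S/W1/W2) use a one-way ANOVA followed,
when the omnibus test is significant at α = 0.05, by pairwise post-hoc
t-tests with the Holm–Šidák step-down correction: sort the m p-values
ascending, adjust the k-th to 1 − (1 − p)^(m−k+1), enforce monotonicity,
cap at 1.  The effect size η² = SS_between/SS_total is always computed; the
report layer shows it only for significant results.  Degenerate inputs are
resolved by convention: identical zero-variance groups compare equal
(t = 0, p = 1; F = 0, η² = 0).  Subjects missing a condition are dropped
listwise from that comparison.

## The synthetic gait generator

The generator exists so that every analysis stage has a recoverable target.
It builds the *kinematic appearance* of steady walking, not its dynamics:

- CoM: constant-speed AP ramp with a small step-frequency fluctuation,
  sinusoidal ML sway at step frequency phased toward the stance foot,
  double-bump vertical oscillation, all blended in smoothly from standing.
  The CoM height is solved numerically so the stance-foot-to-CoM distance
  averages exactly to the configured leg length.
- Feet: constant during stance, C²-smooth (smootherstep) horizontal
  transport during swing with a half-sine height profile whose steep
  touchdown makes the contact sample unambiguous.
- Forces: a two-peak stance profile scaled so the per-stride force impulse
  equals body weight × stance fraction (a contract asserted in the tests),
  crossing 30 N within one insole sample of true contact.
- Jumps: three flight phases (force zero, CoM in free fall) with landing
  spikes, prepended for synchronization; a configurable constant offset
  separates the insole clock.
- Timing: stride time 1.1 s with stance fraction 7/11, chosen so every gait
  event lands exactly on both the 120 Hz and 100 Hz grids.  Defaults for
  stride length (1.61 m), step width (0.09 m) and leg length (0.91 m) are
  typical healthy-adult values consistent with the study population.

Midstance CoM-state deviations are drawn from a configurable 9×9 covariance
(the study never printed a state distribution, so the default diagonal
magnitudes are plausible healthy-walking variabilities — a free modelling
choice) and injected as compactly supported C² bumps centred on each
midstance, carrying prescribed position, velocity and acceleration values
at the bump centre.  One warm-up stride precedes the ground-truth strides
because the first heel strike has no preceding swing and is invisible to
contact detection.

Two self-consistency devices make noiseless recovery exact rather than
approximate.  First, the controller consumes the state *as measured*: the
generator runs the analysis code (same differentiation, interpolation,
anchoring, mirror pooling) on its own sampled signals and sets each
placement deviation to B·(measured state) + noise, so with zero noise the
downstream fit returns B and R² = 1 to machine precision.  Second, the
compensation channels are built from the generator's own stepping-fit
residuals: the CoP offset is drawn freely, the residual at the configured
SD, and the trunk offset solved from the error equation, so the
compensation fit is exact when its residual noise is zero, and the ankle
predictor is exactly null-independent when its gain is zero.  CoP and
trunk offsets are injected as constants over their respective windows, on
top of zero-mean base profiles, so window means recover them exactly.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: physically consistent whole-body dynamics (no
force–motion coupling, no slip mechanics), soft-tissue and sensor-fusion
artefacts of IMU capture, marker dropout, clock drift (the offset is
constant), turning and terrain geometry, and realistic CoM-state spectra
(the injected bumps create short-lived velocity excursions between events;
the ML MoS minima absorb these, so synthetic ML MoS variability is larger
and less realistic than the event-based AP margins).  Recovery results on
the generator validate the estimators, not the biomechanics of any real
population.

## Numerical conventions

- All randomness flows from one integer seed through one
  `numpy.random.Generator`; draws occur in a fixed order regardless of
  configuration branches, so outputs are bit-identical across reruns.
- CSV output uses a fixed 10-significant-digit float format: byte-identical
  reruns, with round-trip perturbations at the 1e-8 level (the in-memory
  path is exact).
- Covariances must be symmetric positive semi-definite (checked by
  eigenvalue, tolerance −1e-10); sampling uses an eigendecomposition square
  root so semi-definite inputs are legal.
- Rank-deficient predictor matrices are rejected with the offending columns
  named; constant compensation predictors likewise.
- Strides missing an interior event are skipped with a logged warning, not
  an error; fits require a minimum of 30 placements by default.

## Problem sizes in the acceptance script

`scripts/acceptance.py` regenerates everything it reports: stepping
recovery uses 25 seeded trials of 400 strides (placement noise set so the
population ML R² is 0.9), the null-ankle calibration 20 trials of 300
strides, the margin-offset recovery two 150-stride trials, the familywise
error simulation 2000 null replicates, and the divergence-exponent checks
30×100-sample periodic series.  These sizes keep the full script to about
a minute on one core; the per-coefficient maximum gain bias remains
Monte-Carlo-limited at this size (its standard error is a few percent for
the weakest-signal coefficient — the mean bias is the stabler summary),
and the test suite runs the stepping and compensation recovery at the full
50 seeds × 500 strides.
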