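# Methods

## Model equations and integration

All units are rate-coded leaky integrators (LINs), `da/dt = (−a + Σxᵢ)/τ`,
integrated with forward Euler at `dt` = 0.1 ms throughout.  τ is a time
constant in the conventional sense: it divides the drive, so a larger τ
means slower dynamics (the 15 ms delay arm is the slow arm).  An equivalent
reading in which τ multiplies the drive would invert that ordering; it is
available behind a `tau_multiplies` switch in the core stepper purely for
comparison and is used nowhere in the model.  All activities and delay
buffers start at zero.  `dt ≤ τ` is enforced (explicit-Euler stability);
halving `dt` changes 2-s trajectories by well under 1%, and the unit tests
pin the stepped solutions against closed-form and dense-step references.

The adaptive photoreceptor stage is

    da_PR/dt = (−a_PR − α + x)/τ_PR        τ_PR = 8 ms
    dα/dt    = (−α + x)/τ_α                τ_α  = 15 ms

a band-pass change detector with zero DC gain (steady state α → x,
a_PR → 0).  Both state variables are advanced from start-of-step values.
Its output is rectified before the correlators; four modes are available
(none / onset-only / offset-only / full), offset-only being the default —
only luminance *decreases* propagate, as one LMC output channel would
carry.  Onset and offset channels give numerically indistinguishable
response curves for symmetric gratings.

## The AVDU

Each detector spans two neighbouring input locations.  Per subunit (fast
and slow), each location contributes a *direct* channel (LIN, τ_b = 1 ms)
and a *delay* channel — a LIN with τ₁ = 5 ms (fast) or τ₂ = 15 ms (slow)
in the dynamical variant, or a sample-aligned delay line of d₁/d₂ ms
followed by a τ_b LIN in the fixed variant.  The correlation is a pointwise
product (no saturating nonlinearity): progressive = delayed(left) ×
direct(right), regressive the mirror image, combined as
`progressive − F·regressive` into a subtraction LIN (τ_R = 5 ms).  F scales
the anti-preferred arm: F = 1 is the classical RHD, F = 0 Zanker's
half-detector; F = 0.25 is the model default, with 0.0 and 0.5 as
experimental variants.

The ratio is taken **after summation over the array** (once per array, not
per detector): `r = Σfast / max(Σslow, 0.01)`, smoothed by a τ_S = 100 ms
LIN.  Only the denominator is floored — the numerator and hence the output
may go negative.  Division-then-smoothing is the implemented order; a
`smooth_before_divide` flag exposes the alternative reading (smooth the two
sums, then divide) without endorsing it.  The fast (smaller-delay) subunit
is always the numerator.

Consequences worth knowing:

* wherever the summed slow response is below the 0.01 floor (low AV, low
  contrast, very small arrays) the output tracks the numerator rather than
  the ratio; the equal-delay "flat response" limit therefore holds only
  above the floor, where it is exact (S ≡ 1);
* the ratio discards the direction selectivity its subunit sums carry: the
  slow arm is the more direction-selective one, so anti-preferred motion
  *raises* the fast/slow ratio even though both sums fall.  This is the
  known directional-tuning cost of ratio-based AV estimation; in closed
  loop it is harmless because forward flight generates only progressive
  flow, but the full detector output should not be used as a direction
  signal.

## Open-loop protocol

Response values are the time-mean of S over the final 1 s of a 2 s run
(steady state is reached well within the first second; doubling the
duration changes the mean by <2%).  Fresh detector state per stimulus.
Sweep grids are log-spaced at 10 points per decade: angular velocity
10–1000 deg/s, temporal frequency 0.25–100 Hz anchored so 10^(k/10) Hz
(including exactly 10 Hz) lie on the grid.  Subunit tuning is probed as the
per-detector mean of the τ_R-filtered subunit outputs, before the division.

On these protocols the tuned model's AV sweep is monotone with logarithmic
adjusted R² ≈ 0.98 (linear ≈ 0.65, exponential ≈ 0.19); the fixed 2/15 ms
variant fits best linearly with a high-AV response ~3.5× the tuned model's;
contrast invariance is exact (the ratio cancels amplitude), and wavelength
invariance holds to CoV < 0.1 at mid AV.  The 15 ms subunit's tuning peak
falls on the 12.6 Hz grid point at all three wavelengths (the 10 Hz
response is within ~3% of that maximum — the curve is nearly flat across
10–16 Hz); the 5 ms subunit peaks one grid step higher at the shorter
wavelengths.  A linearised transfer-function analysis places the slow-arm
peak at 10.4–12.1 Hz depending on wavelength; the square-wave edge
harmonics shift the simulated peak up by about one grid step.

## Curve fitting

Three two-parameter OLS fits: y = a + b·x, y = a + b·ln x, and ln y = a +
b·x over strictly positive responses (log-transformed exponential fit; a
nonlinear variant was considered and not needed).  Adjusted R² = 1 −
(1−R²)(n−1)/(n−2); the best form is the argmax of adjusted R² among
available fits.  Exponential is marked unavailable when fewer than four
responses are positive.

## The virtual world

**Test system** — 100 × 2 input locations, 2° spacing along rows, detectors
along rows; both rows feed one summation stage (198 AVDUs).  Gratings are
point-sampled per location; square waves put the bright half-cycle at
phase 0.

**Full system** — a 32 × 32 ommatidial grid spanning 260° (azimuth) × 180°
(elevation) equirectangularly, centred on the flight axis; row 1 is the
most ventral row, matching the layout convention in which the
column-sensitive subregion is the bottom one.  Subregions (1-based
inclusive): left rows 9–14 × cols 1–12, right rows 9–14 × cols 21–32,
centre rows 1–6 × cols 13–19; all prefer motion away from the frame
centre.  The right block uses columns 21–32 rather than 20–32 so that each
row holds 12 locations and hence the stated 11 detectors.  Counts: 66 / 66
/ 35 AVDUs.

The corridor is 20 cm wide, 20 cm high (height and 300 cm nominal length
are this package's choices; patterns repeat indefinitely along the axis so
trials never run out of corridor).  One ray is cast per ommatidium against
the two walls, floor and ceiling; the first hit's pattern luminance is
returned, and unpatterned surfaces (ceiling, endless ends) return 0.5.
Because the cross-section is constant, hits for a given lateral
position/height are cached and only the pattern evaluation tracks motion —
rendering is exactly deterministic.  No ommatidial acceptance function is
applied (point sampling): the eye's resolution limit is then set by the
8.125° azimuthal ray spacing, and wall patterns finer than ~0.25 c/deg
(bee scale) approach the Nyquist limit, where direction information
genuinely vanishes.  Surface patterns are specified in cycles/deg as seen
from the corridor centre and converted to cycles/cm via the
centre-to-surface distance; because the model eye has ~1/5 the bee's
resolution, experiments present bee-scale frequencies divided by five.
The floor carries a 0.1 c/deg (bee-scale) square wave so the ventral
subregion receives flow for the height controller.

## Closed-loop flight

The controller applies the printed ΔX/ΔZ/ΔV once per control interval,
with sgn(A,A) = 0 on ties; T_X = 1.0, T_Z = 0.5, and T_V = 2·T_X = 2.0
(the velocity setpoint is twice the per-side lateral setpoint, so both are
satisfied simultaneously at the centred equilibrium).  Deltas are in cm
and cm/s per control step; x is kept 0.5 cm off the walls, z 0.5 cm off
floor and ceiling, v ≥ 0.

Two timing choices matter and are this package's own:

* **Control interval 2 ms.**  The printed deltas are per control step, so
  the interval sets every loop gain.  The speed loop is the slowest —
  its time constant is ≈ 264 × the control interval, from the measured
  slope of summed lateral output against speed — and the model's
  validation behaviour (centering from ±3 cm within a 5 s trial, with
  mirrored starting positions converging to the same path) requires that
  loop to settle well inside the trial.  2 ms achieves that (τ_v ≈ 0.5 s)
  while keeping commanded lateral speeds below forward speed; at 10 ms the
  trial ends mid-transient.  The interval is configurable, and must be a
  multiple of the 0.1 ms simulation step.
* **0.5 s sensory warm-up.**  Before control engages, the bee flies
  straight at its entry speed while the adaptation and smoothing filters
  charge.  Without it, the zero-initialised detector reads S ≈ 0, and the
  sgn term drives a large spurious lunge toward the nearer wall during
  filter charge-up; the warm-up models a bee that was already flying when
  it entered the measured section.

Trials: 5 s, entry at ±3 cm lateral, 6 cm height, 40 cm/s; final position
is the mean lateral coordinate over the last 2 s, averaged over the
mirrored pair of starts.  The odometric readout D_E sums S_L + S_R at
control resolution over the whole trial and divides by the along-corridor
distance flown.

## What the virtual world does and does not show

The corridor is a minimal ray-cast renderer standing in a role a full
ray-tracing environment played for the original experiments; its
projection (equirectangular) is a stated choice, not a verified mapping.
Passing closed-loop tests therefore show that the detector + controller
reproduce the *pattern* of behaviours (centering, deviation toward the
higher-frequency wall for F ∈ {0.0, 0.25} and its breakdown at F = 0.5,
mirror symmetry) — not that absolute offsets match field data, which are
figure-level readings.  Known limitations, documented from the closed-loop
analysis:

* With this renderer the summed lateral output reaches the controller
  setpoints only near 115–130 cm/s, so the closed-loop operating speed is
  several times the 40 cm/s entry speed.  The height loop's setpoint
  (T_Z = 0.5 in AV-tuned output units, ≈ 57 deg/s of ventral flow) is then
  unreachable inside a 20 cm-tall corridor and the bee cruises along the
  ceiling clamp.
* At that raised position and speed, wall frequencies ≥ 0.2 c/deg (bee
  scale) push the lateral temporal frequencies beyond the detector band;
  the speed loop can lose its equilibrium, and the odometric readout D_E
  is then far from constant across wall frequencies.  The odometry
  experiment driver reports this honestly rather than masking it.
* Deviation-direction claims are asserted on wall frequencies the 32 × 32
  eye resolves (≤ 0.2 c/deg bee scale against the 0.15 constant wall);
  beyond ~0.25 c/deg the inter-ommatidial phase exceeds ~145° and
  direction recovery is limited by sampling, matching the reported
  inconsistency of the finest test patterns.

## Determinism

The model contains no randomness: identical configurations give bit-
identical trajectories and response curves.  Pseudo-random inputs appear
only in tests (seeded) for linearity/symmetry properties and OLS oracles.
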