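# Methods

## Scope and data model

The pipeline covers four stages, each with a typed container:

1. **Raw signals** (`GrfTrial`, `MarkerTrial`): one trial's vertical GRF at
   1000 Hz and per-leg vertical marker positions at 200 Hz, plus trial
   covariates (subject, RSP model, stiffness category, height offset, belt
   speed, body mass).
2. **Events** (`StanceEvent`): half-open `[touchdown, takeoff)` sample
   intervals with a leg label and the following aerial time.
3. **Per-step metrics and trial rows** (`StepRecord`, `TrialRow`): contact
   time `t_c`, aerial time `t_a`, `f_step = 1/(t_c+t_a)`, contact length
   `L_c = v·t_c`, stance-average vertical force `F_avg` in body weights,
   per-leg trial means and symmetry indices.
4. **Fits** (`CoefTable`, per-speed summaries): REML mixed-model estimates
   with Wald-t inference.

Units are seconds, newtons, metres, Hz and body weights throughout;
indices are 0-based.

## Signal conditioning

**Drift correction.** During flight the true vertical force is zero, so
aerial-phase samples read the transducer baseline directly.  The baseline is
the piecewise-linear interpolant through the median force of each detected
aerial phase (anchored at the phase midpoint, extended flat to the edges),
subtracted from the signal.  Medians rather than means make the anchors
robust to residual noise and to stray samples at the phase borders.  A
signal with fewer than two aerial phases (fully loaded or saturated) has no
baseline information and is rejected.

**Filtering.** Zero-phase (forward–backward) 4th-order Butterworth low-pass,
30 Hz for force and 6 Hz for markers.  Zero-phase application is the norm in
biomechanics because a causal filter would shift event timings; the
effective magnitude response is the squared 4th-order response, and DC gain
is exactly 1, which the tests pin.

**Stance detection.** A 20 N threshold with `>=` on entry and `<` on exit.
Two debounce rules, both configurable: sub-threshold dips shorter than
`min_aerial = 0.02 s` are merged into the surrounding stance (mid-stance
dropouts), and supra-threshold bursts shorter than `min_contact = 0.05 s`
are discarded (spikes, ringing).  The shortest plausible aerial phase at
7 m s⁻¹ is well above 20 ms and the shortest stance well above 50 ms, so
the debounce cannot swallow true phases.  Stances touching either signal
edge are incomplete and dropped.

Detection runs on the **drift-corrected, unfiltered** force.  This is a
deliberate choice: the zero-phase 30 Hz filter spreads the stance flanks by
roughly 3 ms per side, which moves a 20 N crossing outward by ~3 samples at
1000 Hz, whereas on the raw signal the crossing sits within one sample of
the analytic solution for a half-sine stance (the tests verify both
statements).  `F_avg` is then computed from the **filtered** samples within
the detected stance, consistent with filtering force before deriving
metrics.  Because zero-phase filtering preserves impulse, the speed
identity is insensitive to this split.

**Leg labelling.** Marker traces (filtered at 6 Hz) are averaged over each
stance interval with nearest-sample matching between the 200 Hz marker and
1000 Hz force timebases; the leg whose marker is lowest is in contact.
Running steps alternate legs, so an event that resolves to the same leg as
its predecessor is labelled `unknown` and logged rather than guessed.
With no markers at all, labels fall back to strict alternation from a
configurable first leg.

**Saturation.** A trial whose force sits at the configured ceiling for
three or more consecutive samples is flagged saturated and excluded from
aggregation; clipped peaks would bias `F_avg` low.

## Metrics and aggregation

A step is one stance plus its following aerial phase; the final stance of a
trial has no following aerial phase and is dropped.  `L_c = v·t_c` uses the
belt speed as the CoM speed — the standard treadmill surrogate, and the
single largest modelling assumption in the pipeline, since it makes
`L_step = L_c·F_avg` an impulse-balance identity rather than an independent
measurement.  Body-weight normalisation uses g = 9.81 m s⁻² (configurable).

Trial aggregation takes the last 16 labelled steps by default (the
trial-success criterion of the protocol — 16 consecutive steps holding
position on the belt; configurable to all steps), computes per-leg
arithmetic means, and derives each SI from the two per-leg means — not by
averaging per-step SIs, since the index is defined on leg-level quantities.
At least 4 usable steps per leg (configurable) are required.

## Mixed models

Each of the six responses is fit with the same fixed-effect structure
(model, stiffness category, height, speed, and each covariate × speed) and
a subject random intercept, by REML through `statsmodels` `MixedLM`.  The
design matrix is built by hand in a fixed, documented column order with
treatment coding (references: Catapult, −1 stiffness); term names follow
the published row labels (`model [Xtend]`, `stiffness cat [+1]*speed
[m s^-1]`, …) so coefficient tables align with the reference tables
term-for-term.  Speed enters uncentred: the published intercepts (e.g.
0.53 m for affected-leg contact length) are only consistent with speed = 0
extrapolation.  Height offsets pass through as signed, possibly
non-integer, centimetres.

Inference is Wald-t with residual degrees of freedom (n − p).  The original
analysis was run in R and most likely used a Satterthwaite approximation;
with ~700 observations and 12 fixed effects the difference is negligible
for estimates and standard errors, which are the quantities compared.
Confidence intervals are estimate ± t₀.₉₇₅·s.e.  Singular (boundary)
random-intercept variances are flagged in the result rather than rejected.
A response with machine-zero residual variance (noise-free simulation) is
solved exactly by least squares with the inference columns set to NaN.
No multiple-testing correction is applied (single α = 0.05, used only for
reporting annotations).

## The synthetic generator

**Signals.** Stance force is a half-sine, `F(t) = F_peak·sin(πt/t_c)` —
the simplest shape with the correct impulse properties; the pipeline's
metrics depend only on timing and the stance mean, not on shape.  Unless
overridden, `F_peak = (π/2)·m·g·(t_c+t_a)/t_c` enforces impulse balance, so
the truth satisfies `v = L_c·F_avg·f_step` exactly.  Defaults are a 16-step
trial at 3 m s⁻¹ with `t_c = 0.2 s`, `t_a = 0.12 s` (hence `F_avg = 1.6` BW
and `f_step = 3.125` Hz), 76 kg body mass (the published subject-mass
mean).  Between-leg asymmetry applies ±δ multiplicative offsets (unaffected
× (1+δ), affected × (1−δ)) to `t_c`, `t_a` and/or the peak, giving
closed-form truth SIs (e.g. δ = 0.1 on `t_c` → `L_c` SI = +20%).  The
half-sine is evaluated at a half-sample phase offset so the discrete bump
is time-symmetric — touchdowns generically fall between samples.  White
measurement noise, linear or sinusoidal baseline drift, and saturation
clipping are applied after the truth is captured, in that order, mirroring
the physical signal path.  No within-trial step-to-step variability is
simulated (none is reported to calibrate against); `noise_sd` has no
published anchor and is a config parameter, not a constant.  Markers are a
scalar height per leg: 0.05 m during own stance, arcing to 0.15 m
mid-swing — sufficient for leg labelling, which is all the pipeline uses
markers for.

**Trial tables.** The covariate design emulates the published study: 10
subjects × 27 occupied (model × stiffness × height) cells × speeds
3–7 m s⁻¹, including the footnoted non-integer height offsets (−1.8, −1.3,
−1.0, +0.8, +1.0 cm) and the trials lost to saturation or incomplete speed
series — 704 analysed trials in total.  Which specific subjects occupy the
reduced cells is not published; they are assigned deterministically (lowest
ids first), which preserves the count and covariate structure but not the
exact subject-by-cell incidence.  Responses are drawn as linear predictor +
subject intercept + residual, deterministic under the seed.

**What passing tests do and do not show.**  The generator produces ideal
steady running: perfectly periodic steps, exact impulse balance, white
noise, smooth drift.  Passing tests demonstrate that the event detector,
metric definitions, aggregation and model fitting are correct and
internally consistent at the study's sampling rates and design — not that
the pipeline is robust to pathologies absent from the simulation (marker
dropout, partial foot strikes, belt-speed fluctuation, coloured noise).

## Numerical choices and problem sizes

Tolerances pinned by tests: truth speed-identity 1e-9; integrated stance
mean vs inverse duty factor 1e-3 (1000 Hz); detected edges within ±1 sample
of the analytic crossing and ±2 samples of generator truth; measured
per-step identity and duty-factor consistency within 2% (threshold-induced
`t_c` truncation); drift-corrected aerial medians within ±0.5 N under a
10 N ramp; balanced-design mixed-model vs OLS 1e-6; reparameterisation
contrast 1e-8.  Monte-Carlo parameter recovery uses 200 replicates of the
704-row design (≈6 s); coverage is asserted per term at ≥90% for nominal
95% intervals, and bias is asserted below 10% of truth wherever 200
replicates can resolve it (for near-zero published interaction terms the
Monte-Carlo standard error exceeds that bound, so only unbiasedness within
3 MC s.e. is asserted).  Synthetic signal tests use 16-step trials
(~5–6 s of 1000 Hz data each), the design the trial-success criterion
implies.

## Known limitations

* `L_c` is a belt-speed surrogate, not a measured CoM displacement.
* The deposited per-trial table of the original study is not bundled; the
  `reproduce` workflow is exercised against synthetic stand-ins drawn from
  the published coefficients, and accepts the real table via `--table`
  with a column-mapping config.
* Only the vertical force component and scalar vertical marker positions
  are handled; no 3-D kinematics, centre-of-pressure or joint-level
  quantities.
* p-values use residual-df Wald-t, not Satterthwaite; exact p reproduction
  is out of scope.
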