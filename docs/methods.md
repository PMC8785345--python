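# Methods

This note documents the models, estimators, and simulation machinery in
`basaltitrate`: what they assume, the parameters that matter, and the
design choices made where the problem left the design open.

## The glucoregulatory model

The core is a 9-state linear time-invariant model of glucose–insulin–meal
dynamics in type 1 diabetes on MDI therapy: a linearized oral-glucose
minimal model (glucose deviation `x1` and insulin action `x2`), a
two-depot subcutaneous pharmacokinetic chain for long-acting insulin
(precipitate `x3` → soluble `x4` → plasma, as for glargine-100), a
two-compartment subcutaneous chain for rapid insulin (`x5, x6` → plasma
`x7`), and a stomach/gut carbohydrate chain (`x8, x9`) with parallel
absorption into the glucose row. The model output is affine,

    Y(t) = x1(t) + G0,

where the offset `G0` is the subject's *zero-basal-insulin fasting
glucose* (~250 mg/dL for an adult with T1D). Anchoring the level at zero
insulin — rather than at the current therapy — keeps the dose→fasting
relationship absolutely referenced; during development, every anchor tied
to the current dose produced a "treadmill" in the closed loop (the model
implicitly assumed the present dose was already right, which is exactly
what a titration algorithm must not presume).

Doses and meals are impulses injected into the state (a dose at sample k
first affects the output at k+1); the residual metabolic flux ω is a
zero-order-hold disturbance on the glucose-derivative row, integrated
exactly over each sampling step. Discretization is by matrix exponential.
The once-daily periodic steady state has the closed form
`exp(Ac·(t−tB)) (I − exp(Ac·T))⁻¹ B·D`, verified in the tests against
brute-force repeated dosing at 1e−6 relative tolerance.

### Default parameters

Population values live in `defaults.yaml` (units and sources per section)
and were chosen once for physiological plausibility, not fitted:

* glucose effectiveness Sg = 0.008 min⁻¹, insulin action rate
  p2 = 0.012 min⁻¹, plasma clearance kcl = 0.14 min⁻¹, distribution
  volumes Vg = 1.6 dL/kg, Vi = 120 mL/kg;
* insulin sensitivity Si = 800 mL/(U·min) in model units — at 70 kg this
  makes one unit of daily basal insulin lower fasting glucose by
  ≈ 5.4 mg/dL, and makes the model's implied carbohydrate ratio agree
  with the 500-rule to ~15%;
* long-acting PK: bioavailability F = 0.8, precipitate fraction 0.97,
  dissolution ksp = 4·10⁻⁴ min⁻¹, absorption ka = 10⁻³ min⁻¹. These
  give a near-peakless 24 h profile (fasting ripple ≈ ±5 mg/dL at a
  typical dose) while a dose change reaches ≈ 80% of its steady-state
  effect within one 3-day titration cycle. Flatter profiles are possible
  but push the depot time constant far beyond the titration cadence and
  destabilize any run-to-run scheme; this pair is the compromise we
  adopted, and the cohort construction check therefore bounds the
  once-daily ripple rather than asserting a ±2 mg/dL band.

## Identification

Each day is identified on a padded window (6 h head, 2 h tail). The MAP
objective fits one insulin sensitivity per day plus four absorption
parameters per meal, in log space, with log-normal priors centered at
population values (CV 30% for Si, 50% for meal parameters) and an iid
normal likelihood with constant 7% coefficient of variation. The
likelihood weights use the *measured* glucose (floored at 20 mg/dL); this
keeps the noise-free self-consistency exact — data generated at the prior
mean are minimized exactly at the prior mean — and gives hypoglycemic
samples the influence their small absolute errors deserve.

The optimizer is bounded L-BFGS-B with a deterministic three-start
schedule (prior mean, ±1 prior sd) and a batched finite-difference
gradient. The objective itself exploits the model's structure: the output
is exactly affine in Si (Si appears only in the glucose row and glucose
feeds back into nothing), and each meal's glucose contribution has a
closed three-exponential form, so one evaluation costs a few vectorized
exponentials instead of a full simulation. The fast path is algebraically
identical to the matrix-exponential discretization (tested to 1e−8).

The initial state of each window is computed from the *logged* basal dose
history (exact propagation of every recorded injection, with the periodic
steady state of the earliest logged dose before that). The constant-dose
steady-state formula is still exposed and used for predictions, but using
it for identification during titration transients misattributes
insulin-on-board and made the closed loop oscillate.

### Residual signal

After the MAP fit, the residual metabolic flux ω (mg/dL/min, piecewise
constant on a 30-min grid) is recovered by ridge deconvolution with a
second-difference smoothness penalty, using the same CV-scaled weights as
the likelihood. λ = 10⁴ was fixed once by an L-curve-style sweep
(correlation with injected smooth disturbances plateaus there for both
clean and sensor-noise conditions); a tiny identity component (10⁻⁶·λ)
keeps the normal equations well-posed and makes ω → 0 uniformly as
λ → ∞, while leaving the penalty's affine null space effectively free so
ω can carry slow level corrections across sparsely observed stretches.

### Treatment-contaminated samples

Rescue carbohydrates taken for hypoglycemia are not logged by any device.
Their rebounds would be misread as metabolic flux (or as insulin
resistance, which is worse: it reverses the titration direction for
overdosed subjects). The pipeline therefore masks CGM samples for 90 min
after any observed sub-70 mg/dL reading — the lows themselves are kept,
and the overnight window (where the trial's policy never treats) is never
masked, so the strongest overdose signal always survives.

## Meal reconstruction

Meals are rebuilt by inverting the patient's own bolus arithmetic:
`U_meal = max(CR·(U_bolus − (G − Gb)/ISF), 0)` grams, with CR and ISF
taken from the *bolus-calculator settings in use* (they are known to the
pen app). Re-estimating TDI from the logs is deliberately avoided: logged
TDI shrinks exactly when basal is underdosed, which inflates the
reconstructed meals by the same factor and hides the underdose from the
optimizer. Reconstructed sizes are coarse by design; the per-meal
absorption parameters absorb size errors during identification.

Unbolused intake is added by a slope detector (30-min CGM slope
> 1.5 mg/dL/min sustained ≥ 20 min, outside a 120-min post-bolus window;
size guess = rise amplitude × Vg·BW/f). At the default thresholds its
false-positive rate on meal-free days with 10%-MARD sensor noise is below
0.5 detections/day. It reliably finds meal-sized unannounced intake;
15 g rescue boluses of carbohydrate are usually below its threshold,
which is why the masking rule above exists.

## Titration

Per cycle (3 days): each day is identified and deconvolved, the
carbohydrate- and bolus-free fasting profile is predicted as an affine
function of the tested dose (periodic steady-state initialization at the
candidate dose, ω on), and a cost — the blood-glucose risk index
`10·(1.509·((ln g)^1.084 − 5.381))²` summed midnight-to-midnight plus a
night-hypoglycemia hinge `α·max(1 − Y/Gt, 0)` — is minimized by grid
search over ±40% of the current dose in 1% steps (ties break to the
smaller dose). Per-day optima are averaged, rounded to 0.5 U, and passed
through the dead-zone/saturation update Φ (dead zone 0.5 U; saturation
20% of the current dose). The night window is the longest bolus-free
clock interval (margins 60 min after the last evening bolus, 30 min
before the first morning one; fallback 00:00–06:00). α = 100 makes one
night sample 10% under target comparable to a large risk-index term;
larger α converges more conservatively from below.

## The in-silico trial

The virtual cohort reuses the same model class with log-normal parameter
jitter (CV ≈ 25% on rates and Si, 15% on PK, 10% on volumes), body weight
≈ 70 ± 15% kg, zero-basal fasting glucose G0 ≈ 250 mg/dL (CV 12%), and a
basal glucose drawn near the usual fasting target (112 ± 4 mg/dL,
clipped to 104–122) — the cohort is built to represent patients whose
*correct* basal dose produces on-target fasting glucose, which is the
premise of titrating toward a fasting target at all. `U_basal_ss` solves
the periodic steady-state condition exactly (day-mean fasting = basal
glucose); TDI = 2·U_basal_ss, CR and ISF by the 500/1800 rules. Basal
timing alternates 07:00/22:00 by subject id and snaps to a main meal
within ±30 min.

Mechanisms the identification model does *not* know about, so every
algorithm faces model mismatch:

* CGM error: multiplicative AR(1) (lag-1 0.7) scaled to ≈10% MARD,
  clipped to 40–400 mg/dL; SMBG: proportional 5% CV, drawn at 06:00 on
  waking (before any rescue carbohydrates);
* hypoglycemia treatment: per-minute Bernoulli(0.10) below 70 mg/dL with
  a 30-min refractory period and 15 g fast-absorbing rescue carbohydrate;
  never between 00:00 and 06:00 (so ~4% of daytime episodes last
  beyond 30 min, 0.9³⁰);
* hepatic counter-regulation: an extra glucose flux of
  0.1 mg/dL/min per mg/dL below 65 mg/dL. The pure linear model has no
  floor and would otherwise fall below zero under deliberately
  mis-scaled boluses; this is the minimal glucagon-like mechanism that
  keeps deep hypoglycemia bounded;
* variance scenario: randomized meal sizes (daily total 200–300 g, mains
  > 30 g, up to three snacks < 40 g, unannounced), ±40% carbohydrate
  counting error, bolus delays up to 60 min, day-to-day log-normal Si
  (CV 15%) and a dawn-phased intraday sinusoid (±20%).

Trials run five arms (control; SMBG control-to-range; SMBG ILC; the
model-based optimizer with reconstructed carbs; the same with counted
carbs) with 3-day cycles, starting doses altered ±50% (alternating by
subject) and bolus scales counter-altered ∓25%. All behavioral and sensor
streams are keyed by (seed, subject, day, purpose), so arms replay
bit-identical streams. The truth simulator propagates the Si-free states
with an exact one-minute matrix exponential and integrates the glucose
row with a zero-order hold (exact for constant Si, O(dt²) under intraday
modulation).

Default problem sizes for the reproduction script and the end-to-end
tests are 20 subjects and 60 simulated days (90 for the ILC arm) — large
enough for stable cohort medians while keeping a full paired experiment
in the minutes range on one core.

## What passing tests do and do not show

The synthetic cohort shares the estimator's model class, so estimator
self-consistency results (exact noise-free recovery, ~1% median Si error
at 7% CV noise) are inverse-crime results by construction; the sensor,
behavior, counter-regulation and rescue mechanisms add realistic — but
still synthetic — mismatch on top. Real CGM/pen data add failure modes
none of this captures: compression lows, calibration drift, missed pen
primes, exercise, and meals that violate the two-compartment absorption
shape. Results on the virtual cohort bound what the algorithms can do
when their structural assumptions hold, not their clinical performance.

Known limitations, observed in-silico and consistent with the method's
hypoglycemia-averse design: subjects whose bolus therapy is heavily
over-scaled converge to basal doses well below their theoretical
steady-state requirement (the night-targeted optimum genuinely shifts
when boluses overdose meals), and subjects whose basal glucose is far
from the ~112.5 mg/dL risk minimum settle a proportional distance from
their theoretical dose.
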