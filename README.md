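# basaltitrate

Model-based titration of long-acting (basal) insulin for people with type 1
diabetes on multiple daily injections (MDI), using continuous glucose
monitoring (CGM) and smart insulin pen records — together with the two
standard fingerstick-based titration rules it is usually compared against,
and an in-silico trial engine to evaluate all of them.

**Who it is for:** researchers in diabetes technology and glucose control who
want a transparent, testable implementation of run-to-run basal titration —
the estimator, the comparators, and the virtual-patient experiment — in
plain scientific Python.

## The method

The patient record is `𝒟 = {G, U_basal, U_bolus}` on a fixed 5-minute grid.
Each 3-day cycle:

1. **Individualize** a 9-state linear glucoregulatory model (linearized
   oral-glucose minimal model + glargine-like two-depot basal PK + rapid
   insulin and stomach/gut carbohydrate chains) on each day's data by MAP:
   one insulin sensitivity `Si` per day and absorption parameters
   `(f, kq1, kq2, kq12)` per meal, with log-normal priors and a
   constant-CV normal likelihood. Carbohydrates are **not required**: meals
   are reconstructed from the pen log by inverting the patient's bolus
   arithmetic, `U_meal = max(CR·(U_bolus − (G − Gb)/ISF), 0)`, and a slope
   detector adds unbolused intake.
2. **Deconvolve** the residual metabolic flux ω (ridge-regularized, smooth,
   piecewise-constant at 30 min) so the individualized model reproduces the
   observed trace.
3. **Predict** the carbohydrate- and bolus-free fasting profile
   `Y_basal(k; B)` as a function of the basal dose `B` (it is affine in
   `B`), and minimize over an ±40% dose grid (1% steps) the cost

       Σₖ risk(Y_basal(k)) + α · Σ_{k∈night} max(1 − Y_basal(k)/110, 0),

   where `risk(g) = 10·(1.509·((ln g)^1.084 − 5.381))²` is the
   blood-glucose risk index (minimum at 112.5 mg/dL) and the night window
   is detected as the longest bolus-free clock interval.
4. **Update** with the dead-zoned, saturated run-to-run rule
   `B_{c+1} = B_c + Φ(B_opt − B_c)` (dead zone 0.5 U, saturation 20% of the
   current dose), rounded to the 0.5 U pen resolution.

Comparators: a control-to-range rule (decrease 10% of the dose if any
fasting fingerstick < 80 mg/dL, increase 0.5 U per started 20 mg/dL of mean
excess over 130) and an iterative-learning-control (ILC) law driving the
fasting mean to 110 mg/dL with per-subject DC gain 3/BW — both passed
through the same Φ update.

The trial engine builds virtual cohorts from the same model class (plus
sensor noise, hypoglycemia rescue behavior, counter-regulation, counting
errors and insulin-sensitivity variability the estimator does not know
about) and runs five paired arms over 3-day cycles with starting doses
altered ±50%. See `docs/methods.md` for assumptions, parameter defaults
and limitations.

## Worked example

Simulate a control subject for three days, write its records to CSV, and ask
for a recommendation (the `simulate-trial` CLI does the same at cohort
scale):

```
$ basaltitrate recommend --cgm cgm.csv --pen pen.csv --current-dose 20 \
      --algorithm range --smbg 75 --smbg 95 --smbg 110
{
  "B_opt": 18.0,
  "B_next": 18.0
}
```

One fingerstick below 80 mg/dL triggers the control-to-range decrement
(10% of 20 U, floor 1 U → 18 U). The model-based algorithm consumes the raw
records instead:

```
$ basaltitrate recommend --cgm cgm.csv --pen pen.csv --current-dose 20
{
  "B_opt": 22.5,
  "B_next": 22.5,
  "per_day": [12.0, 28.0, 28.0],
  "night_window": [1200.0, 750.0]
}
```

Each observed day is identified separately and contributes its own optimal
dose (here 12, 28, 28 U — the first day's window has little usable head
data); the average, rounded to the pen resolution, is 22.5 U, and the
dead-zone/saturation update accepts it (the change is within 20% of the
current dose). Library use mirrors the CLI:

```python
from basaltitrate import load_series, recommend_dose, load_config
from basaltitrate.params import (population_from_config,
                                 basal_pk_from_config, meal_from_config)

cfg = load_config()
cgm = load_series("cgm.csv", "cgm")
pen = load_series("pen.csv", "pen", reference=cgm.t_ref)
rec = recommend_dose(cgm, pen, current_dose=20.0,
                     pop=population_from_config(cfg),
                     basal_pk=basal_pk_from_config(cfg),
                     meal_pop=meal_from_config(cfg))
print(rec.B_opt, rec.B_next, rec.per_day)
```

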