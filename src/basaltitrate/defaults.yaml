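# Default parameter sets for the linearized glucoregulatory model and the
# titration / identification / trial machinery. Values are population-level
# and are overridden per subject or per deployment via `load_config`.
#
# Units are stated per key. Time unit is minutes throughout.

population:
  source: "linearized subcutaneous oral glucose minimal model (SOGMM) literature; adult T1D population values"
  Sg: 0.008      # glucose effectiveness, 1/min
  Gb: 115.0      # basal (operating-point) glucose, mg/dL
  Vg: 1.6        # glucose distribution volume, dL/kg
  BW: 70.0       # body weight, kg
  p2: 0.012      # insulin action rate, 1/min
  Vi: 120.0      # insulin distribution volume, mL/kg
  kc1: 0.004     # SC rapid insulin, direct absorption to plasma, 1/min
  kc12: 0.020    # SC rapid insulin, compartment 1 -> 2 transfer, 1/min
  kc2: 0.020     # SC rapid insulin, compartment 2 absorption, 1/min
  kcl: 0.140     # plasma insulin clearance, 1/min
  Si: 800.0      # insulin sensitivity, mL/(U*min); scales insulin action on glucose
  G0: 250.0      # zero-basal-insulin fasting glucose, mg/dL (level anchor)

basal_pk:
  source: "glargine-100 subcutaneous absorption modelling (precipitate/soluble two-depot form)"
  F: 0.80              # bioavailability, dimensionless
  precip_fraction: 0.97  # fraction of the dose precipitating at injection site
  ksp: 0.0004          # precipitate -> soluble dissolution rate, 1/min
  ka: 0.001            # soluble depot absorption rate, 1/min

meal:
  source: "oral glucose absorption two-compartment (stomach/gut) parameters, mixed-meal literature"
  f: 0.9         # carbohydrate bioavailability, dimensionless
  kq1: 0.002     # stomach -> plasma direct absorption, 1/min
  kq2: 0.022     # gut absorption, 1/min
  kq12: 0.018    # stomach -> gut transfer, 1/min

rescue_meal:
  source: "fast-acting rescue carbohydrate (glucose tablets), rapid absorption"
  f: 1.0
  kq1: 0.005
  kq2: 0.060
  kq12: 0.090

therapy:
  Gb: 110.0            # therapy-level basal glucose used in meal reconstruction, mg/dL
  bolus_target: 110.0  # bolus-calculator glucose target, mg/dL

identification:
  likelihood_cv: 0.07    # constant CV of the CGM likelihood (fraction of model output)
  prior_cv_si: 0.30      # log-domain prior sd for daily insulin sensitivity
  prior_cv_meal: 0.50    # log-domain prior sd for per-meal absorption parameters
  restarts: 3            # deterministic optimizer restarts: mean, +1 sd, -1 sd
  max_iter: 60           # L-BFGS-B iteration cap per restart
  pad_head_min: 360      # identification window head padding, minutes
  pad_tail_min: 120      # identification window tail padding, minutes
  omega_grid_min: 30     # residual-signal grid resolution, minutes
  omega_lambda: 10000.0    # second-difference regularization weight (L-curve sweep, fixed)

detector:
  slope_threshold: 1.5   # mg/dL/min over a 30-min backward window
  sustain_min: 20        # minutes the slope must stay above threshold
  exclusion_min: 120     # post-bolus exclusion window, minutes

titration:
  Gt: 110.0          # night glucose target, mg/dL
  alpha: 100.0       # night hypoglycemia penalty weight
  grid_span: 0.40    # grid half-width as fraction of the current dose
  grid_step: 0.01    # grid step as fraction of the current dose
  x_min: 0.5         # dead-zone half-width, U
  x_max_frac: 0.20   # saturation as fraction of the current dose, U
  dose_resolution: 0.5  # pen resolution, U
  cycle_days: 3
  night_margin_after_bolus: 60   # minutes after the last evening bolus
  night_margin_before_bolus: 30  # minutes before the first morning bolus

control_to_range:
  G_min: 80.0
  G_max: 130.0

ilc:
  gamma: 1.0
  G_target: 110.0
  filter_pole: 0.5   # first-order low-pass pole; DC gain is individualized to 3/BW

sensors:
  cgm_mard: 0.10   # target mean absolute relative difference of the CGM error model
  cgm_ar1: 0.7     # lag-1 autocorrelation of the CGM additive error
  smbg_cv: 0.05    # proportional SMBG meter error

trial:
  dt: 5.0                  # CGM sampling interval, minutes
  rescue_carbs_g: 15.0
  hypo_threshold: 70.0     # mg/dL
  counterreg_threshold: 65.0   # mg/dL; hepatic counter-regulation kicks in below
  counterreg_gain: 0.10        # mg/dL/min extra glucose flux per mg/dL below threshold
  hypo_treat_prob: 0.10    # per-minute treatment probability below threshold
  hypo_refractory_min: 30
  night_untreated: [0, 360]   # clock minutes during which hypoglycemia is never treated
  cohort_cv: 0.25          # log-normal multiplicative jitter of population parameters
  g0_mean: 250.0           # zero-basal-insulin fasting glucose, mg/dL (cohort draw center)
  g0_cv: 0.12
  gb_mean: 112.0           # subject basal glucose draw, mg/dL
  gb_sd: 4.0
  gb_range: [104.0, 122.0]
  basal_fraction: 0.5      # U_basal_ss / TDI by construction
  si_intraday_amplitude: 0.20   # variance scenario: sinusoidal Si modulation, dawn-phased
  si_day_cv: 0.15               # variance scenario: day-to-day log-normal Si
  meal_times: [420, 780, 1140]  # 07:00, 13:00, 19:00
  nominal_meals_g: [50.0, 75.0, 75.0]
  variance_total_range: [200.0, 300.0]
  variance_main_min_g: 30.0
  variance_snack_max_g: 40.0
  carb_count_error: 0.40        # uniform +/- fraction (variance scenario)
  bolus_delay_max_min: 60.0     # variance scenario
  smbg_clock_min: 360           # 06:00 daily pre-breakfast fingerstick (on waking,
                                # before any rescue carbohydrates are taken)
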