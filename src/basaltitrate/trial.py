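"""In-silico trial engine: virtual T1D cohort, behavior and sensor models,
and the five-arm titration experiment.

The virtual subjects reuse the package's own linear glucoregulatory model
class (which makes noise-free convergence checks exact by construction) but
the trial adds mechanisms the identification model does not know about —
sensor noise, hypoglycemia rescue carbohydrates, carbohydrate-counting
error, bolus delays, and (in the variance scenario) sinusoidal intraday and
log-normal day-to-day insulin-sensitivity fluctuations — so the titration
algorithms always face a degree of model mismatch.

Each subject is characterized by a basal glucose Gb and the daily basal
dose U_basal_ss that sustains it: the model's affine output offset is the
subject's zero-insulin fasting glucose G0, and U_basal_ss solves the
periodic steady-state condition mean-fasting(U) = Gb exactly. TDI is set so
the basal fraction is 50%, and CR/ISF follow the 500- and 1800-rules.

Randomness: one root seed; every (subject, day, purpose) gets its own child
stream, so treatment arms replay bit-identical behavioral streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .comparators import (ControlToRangeConfig, ILCConfig, ILCState,
                          titrate_control_to_range, titrate_ilc)
from .identify import PriorSpec
from .io import DoseEvents, GlucoseSeries
from .meals import DetectorConfig
from .model import build_continuous_model, steady_fasting_mean
from .params import (BasalPKParameters, MealAbsorptionParameters,
                     PopulationParameters, TherapyParameters, load_config,
                     replace)
from .titration import TitrationConfig, recommend_dose

MINUTES_PER_DAY = 1440
ARMS = ("CTR", "SMBG-Rule", "SMBG-ILC", "CGM-Opt", "CGM-Opt-Carb")

# purpose codes for child RNG streams
_P_MEALS, _P_NOISE, _P_TREAT, _P_SMBG, _P_METAB = 0, 1, 2, 3, 4


def _stream(seed: int, subject: int, day: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject, day, purpose])


def _round_dose(x: float, res: float = 0.5) -> float:
    return max(0.0, round(x / res) * res)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class VirtualSubject:
    """Ground-truth parameterization of one virtual patient."""

    id: int
    pop: PopulationParameters            # true (jittered) parameters; pop.Gb is the subject's basal glucose
    basal_pk: BasalPKParameters
    meal: MealAbsorptionParameters
    G0: float                            # zero-basal-insulin fasting glucose, mg/dL (output offset)
    Ubasal_ss: float                     # daily basal dose sustaining Gb, U
    TDI: float
    CR: float
    ISF: float
    basal_time: int                      # clock minutes (07:00 or 22:00)

    @property
    def Gb(self) -> float:
        return self.pop.Gb

    @property
    def BW(self) -> float:
        return self.pop.BW

    def therapy(self, Gb: float = 110.0) -> TherapyParameters:
        return TherapyParameters(TDI=self.TDI, CR=self.CR, ISF=self.ISF, Gb=Gb)


def generate_cohort(n: int, seed: int, cfg: dict | None = None) -> list[VirtualSubject]:
    """Draw ``n`` virtual subjects (deterministic given ``seed``).

    Rates and Si receive log-normal multiplicative jitter (CV ~ 25%) around
    population values; body weight and glycemic anchors get their own draws.
    U_basal_ss is solved from the periodic steady state so that the day-mean
    fasting glucose at that dose equals the subject's basal glucose; basal
    dosing alternates between morning (07:00) and bedtime (22:00) by id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or load_config()
    tr = cfg["trial"]
    from .params import (basal_pk_from_config, meal_from_config,
                         population_from_config)
    pop0 = population_from_config(cfg)
    bas0 = basal_pk_from_config(cfg)
    meal0 = meal_from_config(cfg)
    cv = tr["cohort_cv"]
    rng = np.random.default_rng([seed, 0xC0807])
    subjects: list[VirtualSubject] = []
    for sid in range(n):
        for attempt in range(50):
            j = lambda x, c=cv: float(x * rng.lognormal(-0.5 * c * c, c))  # noqa: E731
            try:
                bw = float(np.clip(70.0 * rng.lognormal(0, 0.15), 45.0, 140.0))
                gb = float(np.clip(rng.normal(tr["gb_mean"], tr["gb_sd"]), *tr["gb_range"]))
                g0 = j(tr["g0_mean"], tr["g0_cv"])
                pop = PopulationParameters(
                    Sg=j(pop0.Sg), Gb=gb, Vg=j(pop0.Vg, 0.10), BW=bw,
                    p2=j(pop0.p2), Vi=j(pop0.Vi, 0.10), kc1=j(pop0.kc1),
                    kc12=j(pop0.kc12), kc2=j(pop0.kc2), kcl=j(pop0.kcl),
                    Si=j(pop0.Si), G0=g0)
                bas = BasalPKParameters(F=bas0.F, precip_fraction=bas0.precip_fraction,
                                        ksp=j(bas0.ksp, 0.15), ka=j(bas0.ka, 0.15))
                meal = MealAbsorptionParameters(
                    f=float(np.clip(j(meal0.f, 0.10), 0.3, 1.2)),
                    kq1=j(meal0.kq1), kq2=j(meal0.kq2), kq12=j(meal0.kq12))
                m = build_continuous_model(pop, bas, meal, output_offset=g0)
                pull_per_unit = -steady_fasting_mean(m, 1.0, dt=30.0)
                if pull_per_unit <= 0:
                    continue
                u_ss = (g0 - gb) / pull_per_unit
                if not 5.0 <= u_ss <= 80.0:
                    continue
                tdi = u_ss / tr["basal_fraction"]
                subjects.append(VirtualSubject(
                    id=sid, pop=pop, basal_pk=bas, meal=meal, G0=g0,
                    Ubasal_ss=u_ss, TDI=tdi, CR=500.0 / tdi, ISF=1800.0 / tdi,
                    basal_time=420 if sid % 2 == 0 else 1320))
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(f"could not draw a valid subject after 50 tries (id {sid})")
    return subjects


# ---------------------------------------------------------------------------
# Scenario and behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Meal/behavior/variability specification of one study scenario."""

    kind: str = "nominal"                        # {"nominal", "variance"}
    meal_times: tuple = (420, 780, 1140)
    nominal_meals_g: tuple = (50.0, 75.0, 75.0)
    total_range: tuple = (200.0, 300.0)
    main_min_g: float = 30.0
    snack_max_g: float = 40.0
    max_snacks: int = 3
    carb_count_error: float = 0.40
    bolus_delay_max: float = 60.0
    si_intraday_amplitude: float = 0.20
    si_day_cv: float = 0.15
    cgm_mard: float = 0.10
    cgm_ar1: float = 0.7
    smbg_cv: float = 0.05
    dt: float = 5.0
    smbg_clock: int = 360
    bolus_target: float = 110.0

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "variance"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")

    @classmethod
    def from_config(cls, cfg: dict, kind: str = "nominal") -> "ScenarioConfig":
        tr, sn = cfg["trial"], cfg["sensors"]
        return cls(kind=kind, meal_times=tuple(tr["meal_times"]),
                   nominal_meals_g=tuple(tr["nominal_meals_g"]),
                   total_range=tuple(tr["variance_total_range"]),
                   main_min_g=tr["variance_main_min_g"],
                   snack_max_g=tr["variance_snack_max_g"],
                   carb_count_error=tr["carb_count_error"],
                   bolus_delay_max=tr["bolus_delay_max_min"],
                   si_intraday_amplitude=tr["si_intraday_amplitude"],
                   si_day_cv=tr["si_day_cv"], cgm_mard=sn["cgm_mard"],
                   cgm_ar1=sn["cgm_ar1"], smbg_cv=sn["smbg_cv"],
                   dt=tr["dt"], smbg_clock=tr["smbg_clock_min"],
                   bolus_target=cfg["therapy"]["bolus_target"])


@dataclass
class DayBehavior:
    """One day's meal/snack/bolus plan (arm-independent)."""

    meals: list           # (minute-of-day, grams_true, grams_counted, bolus_minute)
    snacks: list          # (minute-of-day, grams) — unannounced, unbolused
    si_day_factor: float


def plan_day(scenario: ScenarioConfig, seed: int, subject: int, day: int) -> DayBehavior:
    """Generate the behavioral stream for one subject-day.

    Deterministic given (seed, subject, day); identical across arms.
    """
    rng = _stream(seed, subject, day, _P_MEALS)
    if scenario.kind == "nominal":
        meals = [(t, g, g, t) for t, g in zip(scenario.meal_times, scenario.nominal_meals_g)]
        return DayBehavior(meals=meals, snacks=[], si_day_factor=1.0)

    lo, hi = scenario.total_range
    for _ in range(200):
        total = rng.uniform(lo, hi)
        k = int(rng.integers(0, scenario.max_snacks + 1))
        snack_sizes = rng.uniform(10.0, scenario.snack_max_g, size=k)
        remaining = total - snack_sizes.sum()
        raw = rng.uniform(scenario.main_min_g, 120.0, size=3)
        mains = raw * (remaining / raw.sum())
        if remaining > 3 * scenario.main_min_g and np.all(mains > scenario.main_min_g) \
                and np.all(mains < 200.0):
            break
    else:
        raise RuntimeError("could not satisfy scenario carbohydrate constraints")
    err = rng.uniform(-scenario.carb_count_error, scenario.carb_count_error, size=3)
    delays = rng.uniform(0.0, scenario.bolus_delay_max, size=3)
    meals = [(int(t), float(g), float(g * (1 + e)), int(t + d))
             for t, g, e, d in zip(scenario.meal_times, mains, err, delays)]
    snack_times = np.sort(rng.uniform(540, 1380, size=k)).astype(int)
    snacks = [(int(t), float(g)) for t, g in zip(snack_times, snack_sizes)]
    mrng = _stream(seed, subject, day, _P_METAB)
    si_factor = float(mrng.lognormal(-0.5 * scenario.si_day_cv ** 2, scenario.si_day_cv))
    return DayBehavior(meals=meals, snacks=snacks, si_day_factor=si_factor)


def compute_bolus(carbs_counted: float, G: float, therapy: TherapyParameters,
                  target: float = 110.0, scale: float = 1.0,
                  resolution: float = 0.5) -> float:
    """Standard bolus calculator: carbs/CR plus correction, floored at zero
    and rounded to the pen resolution."""
    raw = carbs_counted / therapy.CR + (G - target) / therapy.ISF
    return _round_dose(max(0.0, raw * scale), resolution)


def hypo_treatments(glucose: np.ndarray, clock_start: float, uniforms: np.ndarray,
                    threshold: float = 70.0, prob: float = 0.10,
                    refractory: int = 30, night: tuple = (0, 360)) -> list[int]:
    """Open-loop hypoglycemia-treatment policy on a minute-level trace.

    For each minute with glucose below ``threshold`` (outside the untreated
    night span) an independent Bernoulli(prob) decides whether a 15 g rescue
    is taken, followed by a refractory period. Returns treatment minutes.
    """
    out, k, n = [], 0, glucose.size
    while k < n:
        clock = (clock_start + k) % MINUTES_PER_DAY
        if glucose[k] < threshold and not (night[0] <= clock < night[1]) \
                and uniforms[k] < prob:
            out.append(k)
            k += refractory
        else:
            k += 1
    return out


def hypo_persistence_probability(n_episodes: int, duration_min: int,
                                 rng: np.random.Generator,
                                 prob: float = 0.10) -> float:
    """Monte-Carlo P(a daytime hypoglycemia stays untreated beyond the given
    duration) under the per-minute treatment model; analytic value is
    (1-prob)^duration."""
    u = rng.random((n_episodes, duration_min))
    treated = (u < prob).any(axis=1)
    return float(1.0 - treated.mean())


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

class SubjectSimulator:
    """Minute-resolution ground-truth simulator for one subject.

    The linear (Si-free) states propagate exactly via a one-minute matrix
    exponential; the glucose deviation integrates its drive with a
    zero-order hold, which keeps the simulator exact for constant Si and
    accurate to O(dt^2) when Si is modulated within the day.

    Below ``counterreg_threshold`` a hepatic counter-regulation flux
    (``counterreg_gain`` mg/dL/min per mg/dL of depth) opposes further
    decline, emulating glucagon-driven endogenous glucose production. The
    identification model does not know this mechanism; it is part of the
    deliberate model mismatch the titration algorithms must absorb.
    """

    RESCUE = MealAbsorptionParameters(f=1.0, kq1=0.005, kq2=0.060, kq12=0.090)

    def __init__(self, subject: VirtualSubject, scenario: ScenarioConfig,
                 counterreg_threshold: float = 65.0, counterreg_gain: float = 0.10):
        self.sub = subject
        self.scenario = scenario
        p, b, m = subject.pop, subject.basal_pk, subject.meal
        r = self.RESCUE
        # linear states: [x2 action, x3 precip, x4 soluble, x5, x6 sc, x7 plasma,
        #                 x8 stomach, x9 gut, r1 rescue stomach, r2 rescue gut]
        L = np.zeros((10, 10))
        L[0, 0] = -p.p2
        L[0, 5] = p.p2 / (p.Vi * p.BW)
        L[1, 1] = -b.ksp
        L[2, 1] = b.ksp
        L[2, 2] = -b.ka
        L[3, 3] = -(p.kc1 + p.kc12)
        L[4, 3] = p.kc12
        L[4, 4] = -p.kc2
        L[5, 2] = b.ka
        L[5, 3] = p.kc1
        L[5, 4] = p.kc2
        L[5, 5] = -p.kcl
        L[6, 6] = -(m.kq1 + m.kq12)
        L[7, 6] = m.kq12
        L[7, 7] = -m.kq2
        L[8, 8] = -(r.kq1 + r.kq12)
        L[9, 8] = r.kq12
        L[9, 9] = -r.kq2
        self.Ad = expm(L)                       # 1-minute step
        self.a1 = math.exp(-p.Sg)
        self.gain = (1.0 - self.a1) / p.Sg
        vg_bw = p.Vg * p.BW
        self.cm = m.f / vg_bw
        self.cr = r.f / vg_bw
        self.kq = (m.kq1, m.kq2, r.kq1, r.kq2)
        self.x1 = 0.0
        self.lin = np.zeros(10)
        self.b_precip = b.precip_fraction * b.F
        self.b_soluble = (1.0 - b.precip_fraction) * b.F
        self.cr_thr = counterreg_threshold
        self.cr_gain = counterreg_gain

    def set_steady_state(self, dose: float, t_B: float, t_0: float) -> None:
        """Start from the periodic steady state of once-daily dosing."""
        m = build_continuous_model(self.sub.pop, self.sub.basal_pk, self.sub.meal,
                                   output_offset=self.sub.G0)
        from .model import steady_state_init
        x9 = steady_state_init(m, dose, t_B=t_B, t_0=t_0)
        self.x1 = float(x9[0])
        self.lin[:] = 0.0
        self.lin[:8] = x9[1:]

    def glucose(self) -> float:
        return self.x1 + self.sub.G0

    def inject_basal(self, dose: float) -> None:
        self.lin[1] += self.b_precip * dose
        self.lin[2] += self.b_soluble * dose

    def inject_bolus(self, dose: float) -> None:
        self.lin[3] += dose

    def inject_meal(self, grams: float) -> None:
        self.lin[6] += grams * 1000.0

    def inject_rescue(self, grams: float) -> None:
        self.lin[8] += grams * 1000.0

    def step(self, si_t: float) -> None:
        """Advance one minute with the instantaneous insulin sensitivity."""
        lin = self.lin
        kq1, kq2, kr1, kr2 = self.kq
        drive = (-si_t * self.sub.pop.Gb * lin[0]
                 + self.cm * (kq1 * lin[6] + kq2 * lin[7])
                 + self.cr * (kr1 * lin[8] + kr2 * lin[9])
                 + self.cr_gain * max(self.cr_thr - (self.x1 + self.sub.G0), 0.0))
        self.x1 = self.a1 * self.x1 + self.gain * drive
        self.lin = self.Ad @ lin


# ---------------------------------------------------------------------------
# Trial loop
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """Everything one subject produced during a trial arm."""

    subject: VirtualSubject
    start_dose: float
    altered_up: bool                      # started at +50% (else -50%)
    truth: np.ndarray = None              # (days, 1440) mg/dL
    cgm: np.ndarray = None                # (days, 1440/dt)
    smbg: np.ndarray = None               # (days,) pre-breakfast fingerstick
    doses_by_day: np.ndarray = None       # basal dose administered each day
    cycle_doses: list = field(default_factory=list)    # dose after each titration
    cycle_bopts: list = field(default_factory=list)    # averaged B_opt per cycle
    cycle_perday: list = field(default_factory=list)   # unrounded per-day optima per cycle
    boluses: list = field(default_factory=list)        # (abs minute, U)
    meals: list = field(default_factory=list)          # (abs minute, grams true, counted, bolused)
    treatments: list = field(default_factory=list)     # abs minutes of rescue carbs
    basal_events: list = field(default_factory=list)   # (abs minute, U)


@dataclass
class TrialResult:
    """Per-subject traces and dose histories for one arm."""

    arm: str
    scenario: ScenarioConfig
    seed: int
    days: int
    cycle_days: int
    records: list[SubjectRecord] = field(default_factory=list)

    def paired_with(self, other: "TrialResult") -> bool:
        return (self.seed == other.seed and self.days == other.days
                and len(self.records) == len(other.records))


def run_trial(cohort: list[VirtualSubject], scenario: ScenarioConfig, arm: str,
              days: int, seed: int, cfg: dict | None = None,
              titration_cfg: TitrationConfig | None = None,
              progress: bool = False) -> TrialResult:
    """Simulate one treatment arm over ``days`` days with 3-day titration.

    Starting doses alternate +50% / -50% of each subject's steady-state
    requirement (even/odd id), with the bolus scale counter-altered by 25%.
    Behavioral and sensor streams depend only on (seed, subject, day), so
    arms are paired exactly.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    tcfg = titration_cfg or TitrationConfig()
    if days % tcfg.cycle_days != 0:
        raise ValueError("days must be a multiple of the cycle length")
    cfg = cfg or load_config()
    result = TrialResult(arm=arm, scenario=scenario, seed=seed, days=days,
                         cycle_days=tcfg.cycle_days)
    for sub in cohort:
        result.records.append(
            _run_subject(sub, scenario, arm, days, seed, cfg, tcfg))
        if progress:
            print(f"[{arm}] subject {sub.id} done", flush=True)
    return result


def _run_subject(sub: VirtualSubject, scenario: ScenarioConfig, arm: str,
                 days: int, seed: int, cfg: dict, tcfg: TitrationConfig) -> SubjectRecord:
    dt = scenario.dt
    n_cgm = int(MINUTES_PER_DAY / dt)
    altered_up = sub.id % 2 == 0
    start_dose = _round_dose(sub.Ubasal_ss * (1.5 if altered_up else 0.5))
    bolus_scale = 0.75 if altered_up else 1.25
    rec = SubjectRecord(subject=sub, start_dose=start_dose, altered_up=altered_up,
                        truth=np.empty((days, MINUTES_PER_DAY)),
                        cgm=np.empty((days, n_cgm)),
                        smbg=np.empty(days),
                        doses_by_day=np.empty(days))
    sim = SubjectSimulator(sub, scenario,
                           counterreg_threshold=cfg["trial"].get("counterreg_threshold", 65.0),
                           counterreg_gain=cfg["trial"].get("counterreg_gain", 0.10))
    sim.set_steady_state(start_dose, t_B=sub.basal_time, t_0=0.0)
    therapy = sub.therapy(Gb=scenario.bolus_target)

    dose = start_dose
    ilc_state = ILCState()
    ar_noise = 0.0
    sd_rel = scenario.cgm_mard / math.sqrt(2.0 / math.pi)
    tr = cfg["trial"]
    hypo_thr, hypo_p = tr["hypo_threshold"], tr["hypo_treat_prob"]
    refractory, rescue_g = tr["hypo_refractory_min"], tr["rescue_carbs_g"]
    night_lo, night_hi = tr["night_untreated"]

    # basal administration aligned to a coincident main meal when applicable
    basal_minute = sub.basal_time
    for mt in scenario.meal_times:
        if abs(mt - sub.basal_time) <= 30:
            basal_minute = mt
            break

    pop_cfg = cfg
    priors = None

    for day in range(days):
        plan = plan_day(scenario, seed, sub.id, day)
        noise_rng = _stream(seed, sub.id, day, _P_NOISE)
        treat_u = _stream(seed, sub.id, day, _P_TREAT).random(MINUTES_PER_DAY)
        smbg_z = _stream(seed, sub.id, day, _P_SMBG).standard_normal()
        z_cgm = noise_rng.standard_normal(n_cgm)
        meals_today = {m[0]: m for m in plan.meals}
        bolus_today = {m[3]: m for m in plan.meals}
        snacks_today = {s[0]: s for s in plan.snacks}
        si_base = sub.pop.Si * plan.si_day_factor
        amp = scenario.si_intraday_amplitude if scenario.kind == "variance" else 0.0
        rec.doses_by_day[day] = dose
        refractory_until = -1
        last_cgm = sub.Gb

        for minute in range(MINUTES_PER_DAY):
            abs_minute = day * MINUTES_PER_DAY + minute
            g_true = sim.glucose()
            rec.truth[day, minute] = g_true

            if minute % int(dt) == 0:
                i = minute // int(dt)
                ar_noise = (scenario.cgm_ar1 * ar_noise
                            + math.sqrt(1 - scenario.cgm_ar1 ** 2) * z_cgm[i])
                last_cgm = float(np.clip(g_true * (1 + sd_rel * ar_noise), 40.0, 400.0))
                rec.cgm[day, i] = last_cgm
            if minute == scenario.smbg_clock:
                rec.smbg[day] = max(20.0, g_true * (1 + scenario.smbg_cv * smbg_z))
            if minute == basal_minute:
                sim.inject_basal(dose)
                rec.basal_events.append((abs_minute, dose))
            if minute in meals_today:
                sim.inject_meal(meals_today[minute][1])
                rec.meals.append((abs_minute, meals_today[minute][1],
                                  meals_today[minute][2], True))
            if minute in snacks_today:
                sim.inject_meal(snacks_today[minute][1])
                rec.meals.append((abs_minute, snacks_today[minute][1], 0.0, False))
            if minute in bolus_today:
                counted = bolus_today[minute][2]
                b = compute_bolus(counted, last_cgm, therapy,
                                  target=scenario.bolus_target, scale=bolus_scale,
                                  resolution=tcfg.dose_resolution)
                if b > 0:
                    sim.inject_bolus(b)
                    rec.boluses.append((abs_minute, b, counted))
            if (g_true < hypo_thr and minute >= refractory_until
                    and not night_lo <= minute < night_hi
                    and treat_u[minute] < hypo_p):
                sim.inject_rescue(rescue_g)
                rec.treatments.append(abs_minute)
                refractory_until = minute + refractory

            si_t = si_base * (1.0 - amp * math.cos(2 * math.pi * (minute - 360) / MINUTES_PER_DAY))
            sim.step(si_t)

        # --- titration on cycle boundaries ---------------------------------
        if (day + 1) % tcfg.cycle_days == 0 and arm != "CTR":
            cyc = slice(day + 1 - tcfg.cycle_days, day + 1)
            if arm == "SMBG-Rule":
                b_opt = titrate_control_to_range(rec.smbg[cyc], dose,
                                                 ControlToRangeConfig(**{k: v for k, v in cfg["control_to_range"].items()}))
            elif arm == "SMBG-ILC":
                icfg = ILCConfig(gamma=cfg["ilc"]["gamma"], G_target=cfg["ilc"]["G_target"],
                                 filter_pole=cfg["ilc"]["filter_pole"])
                b_opt, ilc_state = titrate_ilc(float(np.mean(rec.smbg[cyc])), dose,
                                               sub.BW, icfg, ilc_state)
            else:
                if priors is None:
                    from .params import (basal_pk_from_config, meal_from_config,
                                         population_from_config)
                    pop_id = population_from_config(pop_cfg)
                    bas_id = basal_pk_from_config(pop_cfg)
                    meal_id = meal_from_config(pop_cfg)
                    idc = pop_cfg["identification"]
                    priors = PriorSpec.from_population(
                        pop_id, meal_id, cv_si=idc["prior_cv_si"],
                        cv_meal=idc["prior_cv_meal"], likelihood_cv=idc["likelihood_cv"])
                out = _cgm_optimize(rec, sub, arm, day, dt, dose, cfg, tcfg,
                                    priors, seed)
                b_opt = out.B_opt
                rec.cycle_perday.append(list(out.per_day))
            from .titration import run_to_run_update
            new_dose = run_to_run_update(dose, b_opt, tcfg)
            if not rec.cycle_perday or len(rec.cycle_perday) < len(rec.cycle_bopts) + 1:
                rec.cycle_perday.append([float(b_opt)] * tcfg.cycle_days)
            rec.cycle_bopts.append(float(b_opt))
            rec.cycle_doses.append(new_dose)
            dose = new_dose
        elif (day + 1) % tcfg.cycle_days == 0:
            rec.cycle_perday.append([dose] * tcfg.cycle_days)
            rec.cycle_bopts.append(dose)
            rec.cycle_doses.append(dose)
    return rec


def _cgm_optimize(rec: SubjectRecord, sub: VirtualSubject, arm: str, day: int,
                  dt: float, dose: float, cfg: dict, tcfg: TitrationConfig,
                  priors: PriorSpec, seed: int):
    """Run the model-based optimizer on the closing cycle's data."""
    from .params import (basal_pk_from_config, meal_from_config,
                         population_from_config)
    idc = cfg["identification"]
    det = cfg["detector"]
    n_cgm = rec.cgm.shape[1]
    d_first = day + 1 - tcfg.cycle_days
    # include the previous day when available so the head padding has data
    d_lo = max(0, d_first - 1)
    ts, vs = [], []
    for d in range(d_lo, day + 1):
        ts.append(d * MINUTES_PER_DAY + dt * np.arange(n_cgm))
        vs.append(rec.cgm[d])
    cgm = GlucoseSeries(np.concatenate(ts), np.concatenate(vs), source="cgm")

    ev_t, ev_d, ev_k = [], [], []
    for t, u in rec.basal_events:
        ev_t.append(float(t)); ev_d.append(float(u)); ev_k.append("basal")
    for t, u, _ in rec.boluses:
        ev_t.append(float(t)); ev_d.append(float(u)); ev_k.append("bolus")
    order = np.argsort(ev_t)
    pen = DoseEvents(np.asarray(ev_t)[order], np.asarray(ev_d)[order],
                     np.asarray(ev_k, dtype=object)[order])

    counted = None
    if arm == "CGM-Opt-Carb":
        counted = [(float(t), float(c)) for t, _u, c in rec.boluses
                   if c > 0 and t >= d_first * MINUTES_PER_DAY]

    # The reconstruction inverts the patient's own bolus calculation, so it
    # uses the bolus-calculator settings the pen app actually applies
    # (including the trial's deliberate +/-25% mis-scaling), never a TDI
    # re-estimated from the logs — that would shrink exactly when basal is
    # underdosed and inflate the reconstructed meals.
    bolus_scale = 0.75 if rec.altered_up else 1.25
    therapy = TherapyParameters.from_tdi(sub.TDI * bolus_scale,
                                         Gb=cfg["therapy"]["Gb"])

    rec_days = list(range(d_first, day + 1))
    out = recommend_dose(
        cgm, pen, dose,
        pop=population_from_config(cfg), basal_pk=basal_pk_from_config(cfg),
        meal_pop=meal_from_config(cfg),
        cfg=tcfg, priors=priors,
        detector=DetectorConfig(slope_threshold=det["slope_threshold"],
                                sustain_min=det["sustain_min"],
                                exclusion_min=det["exclusion_min"]),
        dt=dt, pad_head=idc["pad_head_min"], pad_tail=idc["pad_tail_min"],
        omega_lambda=idc["omega_lambda"], omega_grid=idc["omega_grid_min"],
        restarts=idc["restarts"], max_iter=idc["max_iter"],
        counted_carbs=counted, days=rec_days, therapy=therapy)
    return out
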