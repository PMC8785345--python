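"""Run-to-run titration of the long-acting insulin dose.

Each titration cycle (default every 3 days): individualize the model on each
day of the cycle, recover the residual metabolic signal, predict the
carbohydrate- and bolus-free fasting profile as a function of the basal
dose, minimize a glycemic risk cost with an extra night-hypoglycemia
penalty over a +/-40% dose grid (1% steps), average the per-day optima, and
apply a dead-zoned, saturated update

    B_{c+1} = B_c + Phi(B_opt - B_c),

rounded to the pen resolution. The dead zone ignores small corrections; the
saturation caps the per-cycle change (default 20% of the current dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .identify import (DayContext, PriorSpec, ResidualSignal, ThetaEstimate,
                       estimate_residual_signal, fit_daily_parameters)
from .io import DataBundle, DoseEvents, GlucoseSeries, resample_bundle
from .meals import DetectorConfig, detect_unbolused_meals, reconstruct_meals
from .model import build_continuous_model, simulate, steady_state_init
from .params import (BasalPKParameters, MealAbsorptionParameters,
                     PopulationParameters, TherapyParameters, replace)

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class TitrationConfig:
    """Targets, grid, update bounds and cadence of the titration loop."""

    Gt: float = 110.0            # night target, mg/dL
    alpha: float = 100.0         # night-penalty weight
    grid_span: float = 0.40      # +/- fraction of the current dose
    grid_step: float = 0.01
    x_min: float = 0.5           # dead zone, U
    x_max: float | None = None   # saturation, U; None -> x_max_frac * B_c
    x_max_frac: float = 0.20
    dose_resolution: float = 0.5
    cycle_days: int = 3
    night_margin_after_bolus: float = 60.0
    night_margin_before_bolus: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.grid_step <= self.grid_span:
            raise ValueError("require 0 < grid_step <= grid_span")
        if self.x_max is not None and not 0 <= self.x_min < self.x_max:
            raise ValueError("require 0 <= x_min < x_max")
        if self.dose_resolution <= 0:
            raise ValueError("dose_resolution must be > 0")

    def saturation(self, B_c: float) -> float:
        return self.x_max if self.x_max is not None else self.x_max_frac * B_c


@dataclass(frozen=True)
class NightWindow:
    """Clock interval (minutes) used for the night hypoglycemia penalty.

    ``start > end`` means the window wraps midnight.
    """

    start: float
    end: float

    @property
    def duration(self) -> float:
        return (self.end - self.start) % MINUTES_PER_DAY or MINUTES_PER_DAY

    def contains(self, clock: np.ndarray) -> np.ndarray:
        clock = np.asarray(clock) % MINUTES_PER_DAY
        if self.start <= self.end:
            return (clock >= self.start) & (clock < self.end)
        return (clock >= self.start) | (clock < self.end)


DEFAULT_NIGHT = NightWindow(0.0, 360.0)


@dataclass
class DoseRecommendation:
    """Outcome of one titration cycle."""

    B_opt: float                 # averaged and rounded optimal dose, U
    B_next: float                # dose after the dead-zone/saturation update, U
    per_day: list[float] = field(default_factory=list)
    risk_at_opt: float = float("nan")
    night: NightWindow = DEFAULT_NIGHT


def glycemic_risk(g) -> np.ndarray | float:
    """Symmetric blood-glucose risk index.

    risk(g) = 10 * (1.509 * ((ln g)^1.084 - 5.381))^2 — zero at 112.5 mg/dL
    and rising steeply into hypoglycemia, slowly into hyperglycemia.
    """
    g_arr = np.asarray(g, dtype=float)
    if np.any(g_arr <= 0):
        raise ValueError("glucose must be > 0")
    r = 10.0 * (1.509 * (np.log(g_arr) ** 1.084 - 5.381)) ** 2
    return float(r) if np.isscalar(g) else r


def deadzone_saturation(x: float, x_min: float, x_max: float) -> float:
    """Phi: zero inside the dead zone, clipped at the saturation bound."""
    if not 0 <= x_min < x_max:
        raise ValueError("require 0 <= x_min < x_max")
    ax = abs(x)
    if ax < x_min:
        return 0.0
    if ax > x_max:
        return float(np.sign(x) * x_max)
    return float(x)


def run_to_run_update(B_c: float, B_opt: float, cfg: TitrationConfig) -> float:
    """B_{c+1} = B_c + Phi(B_opt - B_c), rounded to the pen resolution."""
    x_max = cfg.saturation(B_c)
    step = deadzone_saturation(B_opt - B_c, cfg.x_min, x_max)
    nxt = B_c + step
    res = cfg.dose_resolution
    return max(0.0, round(nxt / res) * res)


def detect_night_window(bundle: DataBundle, cfg: TitrationConfig | None = None) -> NightWindow:
    """Longest bolus-free clock interval across the observed days.

    Margins are applied after the last evening bolus and before the first
    morning bolus; intervals shorter than 4 h fall back to 00:00-06:00.
    """
    cfg = cfg or TitrationConfig()
    clocks = np.sort(np.unique(bundle.times[bundle.U_bolus > 0] % MINUTES_PER_DAY))
    if clocks.size == 0:
        return DEFAULT_NIGHT
    gaps = np.diff(np.concatenate([clocks, [clocks[0] + MINUTES_PER_DAY]]))
    i = int(np.argmax(gaps))
    start = (clocks[i] + cfg.night_margin_after_bolus) % MINUTES_PER_DAY
    end = (clocks[(i + 1) % clocks.size] - cfg.night_margin_before_bolus) % MINUTES_PER_DAY
    if (end - start) % MINUTES_PER_DAY < 240.0:
        return DEFAULT_NIGHT
    return NightWindow(float(start), float(end))


@dataclass
class FittedDay:
    """One identified day: context, MAP estimate, residual signal, and the
    absolute start minute of the (unpadded) calendar day."""

    ctx: DayContext
    theta: ThetaEstimate
    omega: ResidualSignal
    day_start: float


def predict_fasting_profile(fd: FittedDay, basal_dose: float,
                            pop: PopulationParameters, basal_pk: BasalPKParameters,
                            meal_pop: MealAbsorptionParameters) -> np.ndarray:
    """Fasting-glucose prediction over the identification window.

    Simulates the individualized model with boluses and meals zeroed, the
    estimated residual signal on, and once-daily dosing at the tested dose
    (periodic steady-state initial condition).
    """
    base, unit = _fasting_basis(fd, pop, basal_pk, meal_pop)
    return base + basal_dose * unit


def _fasting_basis(fd: FittedDay, pop, basal_pk, meal_pop):
    """Decompose the fasting prediction as base(k) + dose * unit(k)."""
    ctx = fd.ctx
    level = ctx.output_offset
    m = build_continuous_model(replace(pop, Si=fd.theta.si), basal_pk, meal_pop,
                               output_offset=level, dt=ctx.dt)
    n = ctx.n
    zero = np.zeros(n)
    omega_fine = fd.omega.fine()
    base = simulate(m, np.zeros(9), zero, zero, zero, omega=omega_fine)
    pattern = (ctx.bundle.U_basal > 0).astype(float)
    x0 = steady_state_init(m, 1.0, t_B=ctx.basal_clock,
                           t_0=ctx.bundle.t_start % MINUTES_PER_DAY)
    unit = simulate(m, x0, pattern, zero, zero) - level
    return base, unit


def optimize_basal_dose(days: list[FittedDay], B_c: float, night: NightWindow,
                        cfg: TitrationConfig, pop: PopulationParameters,
                        basal_pk: BasalPKParameters, meal_pop: MealAbsorptionParameters,
                        ) -> DoseRecommendation:
    """Grid-search the risk-plus-night-penalty cost around the current dose.

    Candidates are B_c (1 + j*grid_step), |j*grid_step| <= grid_span. The
    cost sums run midnight to midnight of each fitted day (padding is used
    for state estimation only); ties break toward the smaller dose. Per-day
    optima are averaged arithmetically, then rounded to the pen resolution.
    """
    if not days:
        raise ValueError("empty day list")
    if B_c <= 0:
        raise ValueError("current dose must be > 0")
    steps = int(round(cfg.grid_span / cfg.grid_step))
    factors = 1.0 + cfg.grid_step * np.arange(-steps, steps + 1)
    candidates = B_c * factors

    per_day, costs_at_opt = [], []
    for fd in days:
        base, unit = _fasting_basis(fd, pop, basal_pk, meal_pop)
        times = fd.ctx.bundle.times
        core = (times >= fd.day_start) & (times < fd.day_start + MINUTES_PER_DAY)
        nightmask = core & night.contains(times)
        Y = base[None, :] + candidates[:, None] * unit[None, :]   # (81, n)
        Yc = np.clip(Y, 1.0, None)
        cost = glycemic_risk(Yc[:, core]).sum(axis=1)
        cost = cost + cfg.alpha * np.maximum(1.0 - Yc[:, nightmask] / cfg.Gt, 0.0).sum(axis=1)
        j = int(np.argmin(cost))          # first minimum = smallest dose
        per_day.append(float(candidates[j]))
        costs_at_opt.append(float(cost[j]))

    res = cfg.dose_resolution
    b_opt = round(float(np.mean(per_day)) / res) * res
    b_next = run_to_run_update(B_c, b_opt, cfg)
    return DoseRecommendation(B_opt=b_opt, B_next=b_next, per_day=per_day,
                              risk_at_opt=float(np.mean(costs_at_opt)), night=night)


# ---------------------------------------------------------------------------
# Full pipeline: raw records -> recommendation
# ---------------------------------------------------------------------------

def estimate_tdi(pen: DoseEvents) -> float:
    """Total daily insulin from the pen log (mean over logged days)."""
    if len(pen) == 0 or pen.doses.sum() <= 0:
        raise ValueError("pen log contains no doses")
    days = max(1.0, np.ceil((pen.timestamps.max() - pen.timestamps.min()) / MINUTES_PER_DAY))
    return float(pen.doses.sum() / days)


def recommend_dose(cgm: GlucoseSeries, pen: DoseEvents, current_dose: float, *,
                   pop: PopulationParameters, basal_pk: BasalPKParameters,
                   meal_pop: MealAbsorptionParameters,
                   cfg: TitrationConfig | None = None,
                   priors: PriorSpec | None = None,
                   therapy: TherapyParameters | None = None,
                   detector: DetectorConfig | None = None,
                   dt: float = 5.0,
                   pad_head: float = 360.0, pad_tail: float = 120.0,
                   omega_lambda: float = 1.0e4, omega_grid: float = 30.0,
                   restarts: int = 3, max_iter: int = 60,
                   counted_carbs: list[tuple[float, float]] | None = None,
                   days: list[int] | None = None) -> DoseRecommendation:
    """One full titration cycle from raw CGM and pen records.

    ``counted_carbs`` (list of (absolute minute, grams)) replaces the
    bolus-rule meal reconstruction when carbohydrate records are available;
    the unbolused-meal detector runs either way. ``days`` selects calendar
    day indices; default is the last ``cfg.cycle_days`` complete days of CGM.
    """
    cfg = cfg or TitrationConfig()
    priors = priors or PriorSpec.from_population(pop, meal_pop)
    therapy = therapy or TherapyParameters.from_tdi(estimate_tdi(pen))
    detector = detector or DetectorConfig()

    def _mask_hypo_rebound(bundle, window_min: float = 90.0) -> None:
        """Mask samples shortly after an observed sub-70 episode.

        Rescue carbohydrates taken for hypoglycemia are not logged; the
        rebound they cause would otherwise be misread as metabolic flux.
        The sub-70 samples themselves are kept (they are real glucose).
        """
        low = bundle.G < 70.0
        if not np.any(low):
            return
        k = int(round(window_min / bundle.dt))
        contaminated = np.zeros(bundle.n, dtype=bool)
        for i in np.flatnonzero(low):
            contaminated[i + 1: i + 1 + k] = True
        bundle.G[contaminated & ~low] = np.nan

    if days is None:
        obs_days = np.unique((cgm.timestamps[cgm.valid] // MINUTES_PER_DAY).astype(int))
        days = list(obs_days[-cfg.cycle_days:])
    if not days:
        raise ValueError("no complete days of CGM data")

    fitted: list[FittedDay] = []
    cycle_lo = min(days) * MINUTES_PER_DAY
    cycle_hi = (max(days) + 1) * MINUTES_PER_DAY
    cycle_bundle = resample_bundle(cgm, pen, dt, (cycle_lo, cycle_hi))
    night = detect_night_window(cycle_bundle, cfg)

    for d in days:
        lo = d * MINUTES_PER_DAY - pad_head
        hi = (d + 1) * MINUTES_PER_DAY + pad_tail
        bundle = resample_bundle(cgm, pen, dt, (lo, hi))
        if counted_carbs is None:
            bundle.U_meal = reconstruct_meals(bundle.G, bundle.U_bolus, therapy)
        else:
            meal = np.zeros(bundle.n)
            for t_abs, grams in counted_carbs:
                if lo <= t_abs < hi:
                    i = int(np.clip(round((t_abs - lo) / dt), 0, bundle.n - 1))
                    meal[i] += grams
            bundle.U_meal = meal
        bundle.U_meal = bundle.U_meal + detect_unbolused_meals(
            bundle.G, dt, bundle.U_bolus, detector,
            vg_bw=pop.Vg * pop.BW, f=meal_pop.f)
        _mask_hypo_rebound(bundle)

        basal_log = pen.select("basal")
        history = (basal_log.timestamps, basal_log.doses) if len(basal_log) else None
        ctx = DayContext(bundle, pop, basal_pk, meal_pop, basal_dose=current_dose,
                         dose_history=history)
        theta = fit_daily_parameters(bundle, priors, pop, basal_pk, meal_pop,
                                     restarts=restarts, max_iter=max_iter, context=ctx)
        omega = estimate_residual_signal(bundle, theta, omega_lambda, ctx,
                                         grid_min=omega_grid, cv=priors.cv)
        fitted.append(FittedDay(ctx=ctx, theta=theta, omega=omega,
                                day_start=d * MINUTES_PER_DAY))

    return optimize_basal_dose(fitted, current_dose, night, cfg, pop, basal_pk, meal_pop)
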