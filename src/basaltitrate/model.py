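"""Linearized glucoregulatory model with long-acting insulin pharmacokinetics.

The model is a 9-state linear time-invariant system. State ordering (used
consistently everywhere in the package):

====  =========================================  =========
idx   meaning                                    units
====  =========================================  =========
x1    glucose deviation from operating point     mg/dL
x2    insulin action driver (plasma insulin
      concentration seen by the glucose row)     U/mL
x3    long-acting precipitate depot              U
x4    long-acting soluble depot                  U
x5    rapid insulin SC compartment 1             U
x6    rapid insulin SC compartment 2             U
x7    plasma insulin mass                        U
x8    stomach carbohydrate                       mg
x9    gut carbohydrate                           mg
====  =========================================  =========

Glucose appears from both the stomach (rate kq1) and the gut (rate kq2) in
parallel, scaled by bioavailability f and the distribution volume Vg*BW.
The model output is affine: Y = x1 + output_offset, where the offset pins
the linearization operating point — it is calibrated so that at a reference
basal dose, with no meals or boluses, the fasting output equals the basal
glucose Gb (see ``calibrate_offset``).

Doses and meals are impulses: a dose at sample k is injected into the state
and first affects the output at sample k+1. The residual metabolic signal
``omega`` (mg/dL/min) is a zero-order-hold continuous disturbance on the
glucose-derivative row, integrated exactly over each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .params import BasalPKParameters, MealAbsorptionParameters, PopulationParameters

N_STATES = 9
IDX_GLUCOSE, IDX_ACTION, IDX_PRECIP, IDX_SOLUBLE = 0, 1, 2, 3
IDX_SC1, IDX_SC2, IDX_PLASMA, IDX_STOMACH, IDX_GUT = 4, 5, 6, 7, 8
MG_PER_GRAM = 1000.0
MINUTES_PER_DAY = 1440.0


class ModelConstructionError(ValueError):
    """The continuous matrix is not strictly stable."""


class SimulationError(RuntimeError):
    """The state became non-finite during forward simulation."""


@dataclass
class StateSpaceModel:
    """Continuous and (optionally) discretized matrices with provenance."""

    Ac: np.ndarray
    Bc_basal: np.ndarray
    Bc_bolus: np.ndarray
    Bc_meal: np.ndarray
    Bc_omega: np.ndarray
    output_offset: float
    pop: PopulationParameters
    basal: BasalPKParameters
    meal: MealAbsorptionParameters
    dt: float | None = None
    Ad: np.ndarray | None = None
    Bd_basal: np.ndarray | None = None
    Bd_bolus: np.ndarray | None = None
    Bd_meal: np.ndarray | None = None
    Bd_omega: np.ndarray | None = None
    Cd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.Cd is None:
            self.Cd = np.zeros(N_STATES)
            self.Cd[IDX_GLUCOSE] = 1.0


def build_continuous_model(pop: PopulationParameters,
                           basal: BasalPKParameters,
                           meal: MealAbsorptionParameters,
                           output_offset: float | None = None,
                           dt: float | None = None) -> StateSpaceModel:
    """Assemble the continuous matrices; optionally discretize at ``dt``.

    Raises ``ModelConstructionError`` if any eigenvalue of Ac has a
    nonnegative real part (the basal steady state would not exist).
    """
    vg_bw = pop.Vg * pop.BW       # dL
    vi_bw = pop.Vi * pop.BW       # mL
    A = np.zeros((N_STATES, N_STATES))
    A[IDX_GLUCOSE, IDX_GLUCOSE] = -pop.Sg
    A[IDX_GLUCOSE, IDX_ACTION] = -pop.Si * pop.Gb
    A[IDX_GLUCOSE, IDX_STOMACH] = meal.f * meal.kq1 / vg_bw
    A[IDX_GLUCOSE, IDX_GUT] = meal.f * meal.kq2 / vg_bw
    A[IDX_ACTION, IDX_ACTION] = -pop.p2
    A[IDX_ACTION, IDX_PLASMA] = pop.p2 / vi_bw
    A[IDX_PRECIP, IDX_PRECIP] = -basal.ksp
    A[IDX_SOLUBLE, IDX_PRECIP] = basal.ksp
    A[IDX_SOLUBLE, IDX_SOLUBLE] = -basal.ka
    A[IDX_SC1, IDX_SC1] = -(pop.kc1 + pop.kc12)
    A[IDX_SC2, IDX_SC1] = pop.kc12
    A[IDX_SC2, IDX_SC2] = -pop.kc2
    A[IDX_PLASMA, IDX_SOLUBLE] = basal.ka
    A[IDX_PLASMA, IDX_SC1] = pop.kc1
    A[IDX_PLASMA, IDX_SC2] = pop.kc2
    A[IDX_PLASMA, IDX_PLASMA] = -pop.kcl
    A[IDX_STOMACH, IDX_STOMACH] = -(meal.kq1 + meal.kq12)
    A[IDX_GUT, IDX_STOMACH] = meal.kq12
    A[IDX_GUT, IDX_GUT] = -meal.kq2

    if np.any(np.real(np.linalg.eigvals(A)) >= 0):
        raise ModelConstructionError("continuous matrix is not strictly stable")

    b_basal = np.zeros(N_STATES)
    b_basal[IDX_PRECIP] = basal.precip_fraction * basal.F
    b_basal[IDX_SOLUBLE] = (1.0 - basal.precip_fraction) * basal.F
    b_bolus = np.zeros(N_STATES)
    b_bolus[IDX_SC1] = 1.0
    b_meal = np.zeros(N_STATES)
    b_meal[IDX_STOMACH] = MG_PER_GRAM   # meal input in grams
    b_omega = np.zeros(N_STATES)
    b_omega[IDX_GLUCOSE] = 1.0          # mg/dL/min flux on the glucose row

    model = StateSpaceModel(Ac=A, Bc_basal=b_basal, Bc_bolus=b_bolus,
                            Bc_meal=b_meal, Bc_omega=b_omega,
                            output_offset=pop.Gb if output_offset is None else float(output_offset),
                            pop=pop, basal=basal, meal=meal)
    if dt is not None:
        model = discretize(model, dt)
    return model


def discretize(model: StateSpaceModel, dt: float) -> StateSpaceModel:
    """Zero-order-hold discretization at sampling interval ``dt`` minutes.

    Ad = exp(Ac*dt). Dose and meal impulses are state injections
    (Bd = Bc); the continuous disturbance channel omega is integrated over
    the step: Bd_omega = (integral_0^dt exp(Ac*s) ds) Bc_omega.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = N_STATES
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = model.Ac
    aug[:n, n] = model.Bc_omega
    e = expm(aug * dt)
    model.dt = float(dt)
    model.Ad = e[:n, :n]
    model.Bd_omega = e[:n, n]
    model.Bd_basal = model.Bc_basal.copy()
    model.Bd_bolus = model.Bc_bolus.copy()
    model.Bd_meal = model.Bc_meal.copy()
    return model


def simulate(model: StateSpaceModel, X0: np.ndarray,
             U_basal: np.ndarray, U_bolus: np.ndarray, U_meal: np.ndarray,
             omega: np.ndarray | None = None,
             return_states: bool = False):
    """Forward-simulate the discrete model.

    All input arrays share length n. Returns Y(k) = Cd X(k) + output_offset
    for k = 0..n-1 (an impulse at sample k first shows in Y(k+1)). With
    ``return_states`` the (n+1, 9) state trajectory is returned as well.
    """
    if model.Ad is None:
        raise ValueError("model must be discretized first")
    U_basal = np.asarray(U_basal, float)
    U_bolus = np.asarray(U_bolus, float)
    U_meal = np.asarray(U_meal, float)
    n = U_basal.size
    if not (U_bolus.size == n and U_meal.size == n):
        raise ValueError("input arrays must share length")
    if omega is None:
        omega = np.zeros(n)
    omega = np.asarray(omega, float)
    x = np.asarray(X0, float).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("X0 must be finite")
    Y = np.empty(n)
    states = np.empty((n + 1, N_STATES)) if return_states else None
    Ad, Bb, Bo, Bm, Bw = model.Ad, model.Bd_basal, model.Bd_bolus, model.Bd_meal, model.Bd_omega
    for k in range(n):
        if states is not None:
            states[k] = x
        Y[k] = x[IDX_GLUCOSE] + model.output_offset
        x = Ad @ x + Bb * U_basal[k] + Bo * U_bolus[k] + Bm * U_meal[k] + Bw * omega[k]
        if not np.all(np.isfinite(x)):
            raise SimulationError(f"non-finite state at step {k}")
    if states is not None:
        states[n] = x
        return Y, states
    return Y


def steady_state_init(model: StateSpaceModel, dose: float,
                      t_B: float, t_0: float, T: float = MINUTES_PER_DAY) -> np.ndarray:
    """Periodic steady state for once-daily dosing, evaluated at clock t_0.

    Closed form: X = exp(Ac * elapsed) (I - exp(Ac T))^{-1} Bc_basal * dose,
    with elapsed = (t_0 - t_B) mod T, i.e. the state ``elapsed`` minutes
    after a dose within the periodic regime. elapsed = 0 is the state just
    after an injection.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    eT = expm(model.Ac * T)
    M = np.eye(N_STATES) - eT
    if np.linalg.cond(M) > 1e12:
        raise ModelConstructionError("I - exp(Ac T) is singular; Ac is not stable")
    base = np.linalg.solve(M, model.Bc_basal * dose)
    elapsed = (t_0 - t_B) % T
    if elapsed == 0:
        return base
    return expm(model.Ac * elapsed) @ base


def dose_history_state(model: StateSpaceModel, times: np.ndarray, amounts: np.ndarray,
                       t_eval: float, T: float = MINUTES_PER_DAY) -> np.ndarray:
    """State at ``t_eval`` given the actual logged basal dose history.

    Before the first logged dose the subject is assumed at the periodic
    steady state of that dose; every logged impulse is then propagated
    exactly. This replaces the constant-dose steady-state assumption during
    titration transients, when the depot still reflects earlier doses.
    """
    times = np.asarray(times, float)
    amounts = np.asarray(amounts, float)
    keep = times <= t_eval
    times, amounts = times[keep], amounts[keep]
    if times.size == 0:
        return np.zeros(N_STATES)
    cache: dict[float, np.ndarray] = {}

    def prop(gap: float) -> np.ndarray:
        key = round(gap, 6)
        if key not in cache:
            cache[key] = expm(model.Ac * gap)
        return cache[key]

    eT = expm(model.Ac * T)
    # just-after-dose periodic state at the first logged dose size
    x = np.linalg.solve(np.eye(N_STATES) - eT, model.Bc_basal * amounts[0])
    for i in range(1, times.size):
        x = prop(times[i] - times[i - 1]) @ x + model.Bc_basal * amounts[i]
    return prop(t_eval - times[-1]) @ x


def steady_fasting_mean(model: StateSpaceModel, dose: float,
                        dt: float = 5.0, T: float = MINUTES_PER_DAY) -> float:
    """Day-mean of Cd X(t) at the periodic steady state for a daily dose.

    This is the fasting glucose deviation (before the affine offset) that
    the dose sustains; it is linear in the dose.
    """
    x = steady_state_init(model, dose, t_B=0.0, t_0=0.0, T=T)
    n = int(round(T / dt))
    Ad = expm(model.Ac * dt)
    total = 0.0
    for _ in range(n):
        total += x[IDX_GLUCOSE]
        x = Ad @ x
    return total / n


def calibrate_offset(model: StateSpaceModel, reference_dose: float,
                     Gb: float | None = None) -> StateSpaceModel:
    """Pin the affine output offset at a reference basal dose.

    Sets output_offset so that the day-mean fasting output at the periodic
    steady state of ``reference_dose`` (no meals, no boluses) equals Gb.
    """
    target = model.pop.Gb if Gb is None else float(Gb)
    model.output_offset = target - steady_fasting_mean(model, reference_dose)
    return model
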