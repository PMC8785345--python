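"""Model individualization: MAP estimation of daily insulin sensitivity and
per-meal absorption parameters, then regularized deconvolution of the
residual metabolic signal.

Estimation model
----------------
Parameters theta = (Si for the day; f, kq1, kq2, kq12 per meal) are fitted
in log space by maximizing a normal likelihood (iid, constant coefficient of
variation, weights taken at the measured glucose) times a log-normal prior
centered at (personalizable) population values. The residual signal omega is
fixed at zero during this step and recovered afterwards by ridge-regularized
deconvolution with a second-difference smoothness penalty on a coarse grid.

Fast path
---------
The model output is exactly affine in Si once the insulin states are known
(Si appears only in the glucose row, and glucose feeds back into nothing),
and each meal's glucose contribution has a closed three-exponential form
(stomach/gut chain filtered by the glucose-effectiveness pole). The
objective therefore costs two 9-state simulations up front and only a few
vectorized exponentials per evaluation. The fast path is algebraically
identical to the matrix-exponential discretization in ``model.simulate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import (IDX_GLUCOSE, StateSpaceModel, build_continuous_model,
                    simulate, steady_state_init)
from .params import (BasalPKParameters, MealAbsorptionParameters,
                     PopulationParameters, replace)

GLUCOSE_FLOOR = 20.0   # mg/dL floor for CV-scaled weights


@dataclass(frozen=True)
class PriorSpec:
    """Log-domain normal priors and the likelihood coefficient of variation.

    ``si_log_mean``/``meal_log_mean`` are the personalization hooks: per
    subject they default to population values but may be re-centered.
    """

    si_log_mean: float
    si_log_sd: float
    meal_log_mean: np.ndarray   # log (f, kq1, kq2, kq12)
    meal_log_sd: np.ndarray
    cv: float = 0.07

    def __post_init__(self) -> None:
        object.__setattr__(self, "meal_log_mean", np.asarray(self.meal_log_mean, float))
        object.__setattr__(self, "meal_log_sd", np.asarray(self.meal_log_sd, float))
        if self.si_log_sd <= 0 or np.any(self.meal_log_sd <= 0):
            raise ValueError("prior sds must be > 0")
        if not 0 < self.cv < 0.5:
            raise ValueError("likelihood CV must be in (0, 0.5)")

    @classmethod
    def from_population(cls, pop: PopulationParameters, meal: MealAbsorptionParameters,
                        cv_si: float = 0.30, cv_meal: float = 0.50,
                        likelihood_cv: float = 0.07) -> "PriorSpec":
        return cls(si_log_mean=float(np.log(pop.Si)), si_log_sd=cv_si,
                   meal_log_mean=np.log([meal.f, meal.kq1, meal.kq2, meal.kq12]),
                   meal_log_sd=np.full(4, cv_meal), cv=likelihood_cv)

    def vectors(self, n_meals: int) -> tuple[np.ndarray, np.ndarray]:
        """Parameter layout: [log Si, (log f, log kq1, log kq2, log kq12)*]."""
        mu = np.concatenate([[self.si_log_mean], np.tile(self.meal_log_mean, n_meals)])
        sd = np.concatenate([[self.si_log_sd], np.tile(self.meal_log_sd, n_meals)])
        return mu, sd


@dataclass
class ThetaEstimate:
    """Per-day MAP estimate: one Si plus absorption parameters per meal."""

    si: float
    meal_indices: np.ndarray          # bundle sample index of each meal impulse
    meal_grams: np.ndarray
    meal_params: list[MealAbsorptionParameters]
    nlp: float                        # negative log posterior at the optimum
    n_iter: int
    converged: bool
    theta_log: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ResidualSignal:
    """Piecewise-constant residual metabolic flux on a coarse grid."""

    omega: np.ndarray       # mg/dL/min per coarse block
    grid_min: float
    lam: float
    n_fine: int
    block: int              # fine samples per coarse block

    def fine(self) -> np.ndarray:
        """Expand to the fine (bundle) grid."""
        return np.repeat(self.omega, self.block)[: self.n_fine]


class DayContext:
    """Precomputed affine basis for one identification window.

    Output decomposition for parameters (Si, per-meal params):
        Y(k) = alpha(k) + Si * beta(k) + sum_m meal_m(k)
    where alpha/beta come from two exact simulations (Si = 0 and Si = 1) of
    the basal+bolus channel, initial state per the periodic steady state at
    the window's basal dose, and meal_m is the closed-form response below.
    """

    def __init__(self, bundle, pop: PopulationParameters, basal_pk: BasalPKParameters,
                 meal_pop: MealAbsorptionParameters, *,
                 output_offset: float | None = None,
                 basal_dose: float | None = None,
                 basal_clock: float | None = None,
                 dose_history: tuple[np.ndarray, np.ndarray] | None = None):
        self.bundle = bundle
        self.pop = pop
        self.basal_pk = basal_pk
        self.meal_pop = meal_pop
        self.dt = bundle.dt
        self.n = bundle.n
        self.vg_bw = pop.Vg * pop.BW

        basal_idx = np.flatnonzero(bundle.U_basal > 0)
        if basal_dose is None:
            basal_dose = float(bundle.U_basal[basal_idx[-1]]) if basal_idx.size else 0.0
        if basal_clock is None:
            if basal_idx.size:
                basal_clock = float(bundle.times[basal_idx[-1]] % 1440.0)
            else:
                basal_clock = 0.0
        self.basal_dose = basal_dose
        self.basal_clock = basal_clock

        # basal/bolus response basis at Si = 0 and Si = 1 (output is affine
        # in Si); initial state from the logged dose history when available
        zero = np.zeros(self.n)
        ys = []
        for si in (0.0, 1.0):
            m = build_continuous_model(replace(pop, Si=si), basal_pk, meal_pop,
                                       output_offset=0.0, dt=self.dt)
            if dose_history is not None:
                from .model import dose_history_state
                x0 = dose_history_state(m, dose_history[0], dose_history[1],
                                        bundle.t_start)
            else:
                x0 = steady_state_init(m, basal_dose, t_B=basal_clock,
                                       t_0=bundle.t_start % 1440.0)
            ys.append(simulate(m, x0, bundle.U_basal, bundle.U_bolus, zero))
        self.alpha_raw, beta_raw = ys[0], ys[1] - ys[0]
        self.beta = beta_raw
        if output_offset is None:
            output_offset = self._anchor_offset(bundle, pop, basal_pk, meal_pop,
                                                basal_dose, basal_clock, dose_history)
        self.output_offset = float(output_offset)
        self.alpha = self.alpha_raw + self.output_offset

        self.meal_indices = np.flatnonzero(bundle.U_meal > 0)
        self.meal_grams = bundle.U_meal[self.meal_indices]
        self.n_meals = self.meal_indices.size
        self.mask = bundle.mask
        g = np.where(self.mask, bundle.G, np.nan)
        self.G = g
        self.weights_base = np.maximum(np.nan_to_num(g, nan=GLUCOSE_FLOOR), GLUCOSE_FLOOR)

    def _anchor_offset(self, bundle, pop, basal_pk, meal_pop,
                       basal_dose, basal_clock, dose_history) -> float:
        """Pin the output level at the zero-basal fasting glucose G0.

        The affine offset is the glucose the subject would settle at with no
        basal insulin at all — a dose-independent subject property (the
        uncontrolled-T1D fasting level). Using it as the anchor keeps the
        dose -> fasting line absolutely referenced; the MAP level-shift
        parameter and the residual signal correct it per subject. Anchors
        tied to the current dose are deliberately avoided: they assume the
        present therapy is already correct, which is exactly what titration
        must not presume.
        """
        return pop.G0

    # -- closed-form meal response ------------------------------------
    def meal_response_batch(self, idx: int, grams: float, f, kq1, kq2, kq12) -> np.ndarray:
        """Glucose contribution (mg/dL) of one meal impulse for a batch of
        parameter draws; exact under the matrix-exponential discretization.

        Parameters are 1-D arrays of equal batch size B; returns (B, n).
        """
        f, kq1, kq2, kq12 = (np.atleast_1d(np.asarray(v, float)) for v in (f, kq1, kq2, kq12))
        B = f.size
        n, dt = self.n, self.dt
        out = np.zeros((B, n))
        start = idx + 1          # impulse convention: injected into X(idx+1)
        if start >= n:
            return out
        t = dt * np.arange(n - start)
        r1 = self.pop.Sg
        r2 = kq1 + kq12
        r3 = kq2.copy()
        # nudge exact eigenvalue collisions off the degenerate manifold
        r3 = np.where(np.abs(r2 - r3) < 1e-12, r3 * (1 + 1e-9) + 1e-15, r3)
        e1 = np.exp(-r1 * t)[None, :]

        def E(r):
            r = np.where(np.abs(r1 - r) < 1e-12, r + 1e-9 * r1 + 1e-15, r)
            return (np.exp(-r[:, None] * t[None, :]) - e1) / (r1 - r)[:, None]

        d_mg = grams * 1000.0
        c = (f / self.vg_bw)[:, None]
        E2, E3 = E(r2), E(r3)
        x1 = c * d_mg * (kq1[:, None] * E2
                         + (kq2 * kq12 / (r2 - r3))[:, None] * (E3 - E2))
        out[:, start:] = x1
        return out

    def output_batch(self, thetas: np.ndarray) -> np.ndarray:
        """Model outputs (B, n) for a (B, P) batch of parameter vectors.

        Layout: theta[0] = log Si, then (log f, log kq1, log kq2, log kq12)
        per meal.
        """
        TH = np.atleast_2d(np.asarray(thetas, float))
        si = np.exp(TH[:, 0])
        Y = self.alpha[None, :] + si[:, None] * self.beta[None, :]
        for m in range(self.n_meals):
            f, kq1, kq2, kq12 = np.exp(TH[:, 1 + 4 * m: 5 + 4 * m]).T
            Y = Y + self.meal_response_batch(self.meal_indices[m], self.meal_grams[m],
                                             f, kq1, kq2, kq12)
        return Y

    def output(self, theta_log: np.ndarray) -> np.ndarray:
        """Model output Y(k) for a log-parameter vector."""
        return self.output_batch(theta_log)[0]

    def omega_matrix(self, grid_min: float) -> tuple[np.ndarray, int]:
        """Map from coarse piecewise-constant omega to glucose contributions.

        The omega channel enters the glucose-derivative row; under the
        zero-order-hold discretization a unit flux during fine step j adds
        g0 * a^(k-1-j) to x1(k), with a = exp(-Sg dt), g0 = (1-a)/Sg.
        """
        n, dt = self.n, self.dt
        block = max(1, int(round(grid_min / dt)))
        m = int(np.ceil(n / block))
        a = np.exp(-self.pop.Sg * dt)
        g0 = (1 - a) / self.pop.Sg
        # fine kernel: contribution of fine step j to sample k (k > j)
        ks = np.arange(n)
        H = np.zeros((n, m))
        pow_a = a ** ks          # a^0 .. a^{n-1}
        for j_block in range(m):
            col = np.zeros(n)
            j_lo, j_hi = j_block * block, min(n, (j_block + 1) * block)
            for j in range(j_lo, j_hi):
                col[j + 1:] += g0 * pow_a[: n - j - 1]
            H[:, j_block] = col
        return H, block


def _nlp_batch(thetas: np.ndarray, ctx: DayContext, priors: PriorSpec) -> np.ndarray:
    """Vectorized negative log posterior for a (B, P) batch."""
    TH = np.atleast_2d(np.asarray(thetas, float))
    mu, sd = priors.vectors(ctx.n_meals)
    prior = 0.5 * np.sum(((TH - mu) / sd) ** 2, axis=1)
    mask = ctx.mask
    if not np.any(mask):
        return prior
    Y = ctx.output_batch(TH)
    r = (ctx.G[mask][None, :] - Y[:, mask]) / (priors.cv * ctx.weights_base[mask])[None, :]
    return 0.5 * np.sum(r * r, axis=1) + prior


def negative_log_posterior(theta_log: np.ndarray, ctx: DayContext,
                           priors: PriorSpec) -> float:
    """- log posterior up to a constant (omega fixed at zero).

    Likelihood: iid normal with sd = CV x measured glucose (floored); masked
    samples are skipped, so with no valid samples this is the prior alone.
    """
    return float(_nlp_batch(theta_log, ctx, priors)[0])


def _fd_value_grad(x: np.ndarray, ctx: DayContext, priors: PriorSpec,
                   eps: float = 1e-6) -> tuple[float, np.ndarray]:
    """Objective and forward-difference gradient in one batched evaluation."""
    TH = np.vstack([x, x[None, :] + eps * np.eye(x.size)])
    v = _nlp_batch(TH, ctx, priors)
    return float(v[0]), (v[1:] - v[0]) / eps


def fit_daily_parameters(bundle, priors: PriorSpec, pop: PopulationParameters,
                         basal_pk: BasalPKParameters, meal_pop: MealAbsorptionParameters,
                         *, restarts: int = 3, max_iter: int = 60,
                         context: DayContext | None = None) -> ThetaEstimate:
    """MAP fit of one identification window (a padded day).

    Bounded quasi-Newton in log space with a deterministic restart schedule
    (prior mean, then +1 and -1 prior sd on every coordinate). Returns the
    best restart; non-convergence is flagged, not raised.
    """
    ctx = context or DayContext(bundle, pop, basal_pk, meal_pop)
    mu, sd = priors.vectors(ctx.n_meals)
    lo = mu - 4.0 * sd
    hi = mu + 4.0 * sd
    if ctx.n_meals:
        # carbohydrate bioavailability is capped at 1.2 by its invariant
        f_slots = 1 + 4 * np.arange(ctx.n_meals)
        hi[f_slots] = np.minimum(hi[f_slots], np.log(1.2))
    bounds = list(zip(lo, hi))

    starts = [mu]
    if restarts >= 2:
        starts.append(np.minimum(mu + sd, hi))
    if restarts >= 3:
        starts.append(np.maximum(mu - sd, lo))

    def fun_grad(x):
        return _fd_value_grad(x, ctx, priors)

    best = None
    total_iter = 0
    for x0 in starts[:max(1, restarts)]:
        res = minimize(fun_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-7})
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and best.status != 1:   # status 1 = maxiter reached
        warnings.warn(f"MAP fit did not converge: {best.message}", RuntimeWarning)

    theta = best.x
    meal_params = []
    for m in range(ctx.n_meals):
        f, kq1, kq2, kq12 = np.exp(theta[1 + 4 * m: 5 + 4 * m])
        meal_params.append(MealAbsorptionParameters(f=min(f, 1.2), kq1=kq1, kq2=kq2, kq12=kq12))
    return ThetaEstimate(si=float(np.exp(theta[0])), meal_indices=ctx.meal_indices.copy(),
                         meal_grams=ctx.meal_grams.copy(), meal_params=meal_params,
                         nlp=float(best.fun), n_iter=int(total_iter),
                         converged=bool(best.success or best.status == 1),
                         theta_log=theta.copy())


def estimate_residual_signal(bundle, theta: ThetaEstimate, lam: float,
                             ctx: DayContext, grid_min: float = 30.0,
                             cv: float = 0.07) -> ResidualSignal:
    """Ridge deconvolution of the residual metabolic flux omega.

    Solves  min_w ||W (G - Y_theta - H w)||^2 + lam (||D2 w||^2 + eps||w||^2)
    in closed form, with w piecewise constant on the coarse grid and D2 the
    second difference. W carries the same constant-CV measurement weights as
    the MAP likelihood (masked samples get zero weight), so low-glucose
    samples are not outvoted by large excursions. The small identity
    component (eps = 1e-6) anchors the penalty's affine null space so
    omega -> 0 uniformly as lam grows.
    """
    Y = ctx.output(theta.theta_log)
    mask = ctx.mask
    r = np.where(mask, np.nan_to_num(ctx.G) - Y, 0.0)
    w_meas = np.where(mask, 1.0 / (cv * ctx.weights_base), 0.0)
    H, block = ctx.omega_matrix(grid_min)
    m = H.shape[1]
    Hm = H * w_meas[:, None]
    D2 = np.zeros((max(m - 2, 0), m))
    for i in range(m - 2):
        D2[i, i: i + 3] = (1.0, -2.0, 1.0)
    A = Hm.T @ Hm + lam * (D2.T @ D2 + 1e-6 * np.eye(m))
    b = Hm.T @ (w_meas * r)
    try:
        cond = np.linalg.cond(A)
        if cond > 1e13:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular deconvolution normal equations; increase lambda") from exc
    return ResidualSignal(omega=w, grid_min=grid_min, lam=lam,
                          n_fine=ctx.n, block=block)
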