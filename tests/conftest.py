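"""Shared fixtures: population parameters and an inverse-crime day generator.

The day generator produces a padded identification window (6 h head, 2 h
tail) from the package's own discrete model — the exact model class the
estimator assumes — with three bolused meals and once-daily basal dosing.
Estimator self-consistency tests (parameter recovery, deconvolution) build
on it; model-mismatch behaviour is exercised separately through the trial
engine.
"""

from __future__ import annotations

import numpy as np
import pytest

from basaltitrate import (PriorSpec, build_continuous_model, load_config,
                          simulate, steady_state_init)
from basaltitrate.io import DataBundle
from basaltitrate.params import (basal_pk_from_config, meal_from_config,
                                 population_from_config, replace)

DT = 5.0
PAD_HEAD, PAD_TAIL = 360.0, 120.0


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def pop(cfg):
    return population_from_config(cfg)


@pytest.fixture(scope="session")
def basal_pk(cfg):
    return basal_pk_from_config(cfg)


@pytest.fixture(scope="session")
def meal_pop(cfg):
    return meal_from_config(cfg)


@pytest.fixture(scope="session")
def priors(pop, meal_pop):
    return PriorSpec.from_population(pop, meal_pop)


@pytest.fixture(scope="session")
def model5(pop, basal_pk, meal_pop):
    return build_continuous_model(pop, basal_pk, meal_pop, dt=DT)


class DayFactory:
    """Build synthetic padded-day bundles from the model itself."""

    def __init__(self, pop, basal_pk, meal_pop):
        self.pop, self.basal_pk, self.meal_pop = pop, basal_pk, meal_pop
        self.dt = DT
        self.t_start = -PAD_HEAD
        self.n = int((PAD_HEAD + 1440 + PAD_TAIL) / DT)
        times = self.t_start + DT * np.arange(self.n)
        self.times = times
        self.basal_dose = 24.0
        self.basal_clock = 420.0
        self.U_basal = np.zeros(self.n)
        self.U_basal[np.isclose(times % 1440, self.basal_clock)] = self.basal_dose
        self.meal_slots = [int((t - self.t_start) / DT) for t in (420.0, 780.0, 1140.0)]
        self.meal_grams = [50.0, 75.0, 75.0]

    def bundle(self, si_factor: float = 1.0, omega: np.ndarray | None = None,
               noise_cv: float = 0.0, seed: int = 0, with_meals: bool = True,
               rescale_bolus: float = 1.0) -> tuple[DataBundle, float]:
        """Return (bundle, true Si). Data generated at the estimator's own
        level anchor (output offset = population G0), so the level-shift
        truth is zero."""
        pop_t = replace(self.pop, Si=self.pop.Si * si_factor)
        m = build_continuous_model(pop_t, self.basal_pk, self.meal_pop,
                                   output_offset=self.pop.G0, dt=self.dt)
        U_bolus = np.zeros(self.n)
        U_meal = np.zeros(self.n)
        if with_meals:
            for i, g in zip(self.meal_slots, self.meal_grams):
                U_meal[i] = g
                U_bolus[i] = round(2 * g / 10.0) / 2 * rescale_bolus
        x0 = steady_state_init(m, self.basal_dose, t_B=self.basal_clock,
                               t_0=self.t_start % 1440.0)
        Y = simulate(m, x0, self.U_basal, U_bolus, U_meal, omega=omega)
        G = Y.copy()
        if noise_cv > 0:
            rng = np.random.default_rng(seed)
            G = Y * (1 + noise_cv * rng.standard_normal(self.n))
        b = DataBundle(G=G, U_basal=self.U_basal.copy(), U_bolus=U_bolus,
                       U_meal=U_meal, dt=self.dt, t_start=self.t_start)
        return b, pop_t.Si


@pytest.fixture(scope="session")
def day_factory(pop, basal_pk, meal_pop):
    return DayFactory(pop, basal_pk, meal_pop)
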