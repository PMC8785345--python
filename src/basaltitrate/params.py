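"""Parameter containers and configuration loading.

All model parameters live in ``defaults.yaml`` (one section per parameter
group, each with a ``source`` citation string) and are materialized here as
frozen dataclasses. Nothing in the algorithm logic hard-codes a population
value; tests are written to be parameter-value-agnostic.

Units: time in minutes, glucose in mg/dL, insulin in U, carbohydrates in
grams at the interface (milligrams inside the state vector).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping

import yaml


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load the package defaults, optionally overlaid with a user YAML file.

    The overlay is a shallow per-section merge: keys present in the user file
    replace the corresponding default keys, section by section.
    """
    text = resources.files(__package__).joinpath("defaults.yaml").read_text()
    cfg: dict[str, Any] = yaml.safe_load(text)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section in cfg and isinstance(cfg[section], dict) and isinstance(values, Mapping):
                cfg[section] = {**cfg[section], **values}
            else:
                cfg[section] = values
    return cfg


class ParameterError(ValueError):
    """A parameter value violates its physiological invariant."""


@dataclass(frozen=True)
class PopulationParameters:
    """Population-level glucoregulatory parameters.

    ``Si`` scales insulin action in the glucose row and carries model units
    of mL/(U*min): (insulin action state) x (Si * Gb) has units mg/dL/min.
    """

    Sg: float   # 1/min
    Gb: float   # mg/dL
    Vg: float   # dL/kg
    BW: float   # kg
    p2: float   # 1/min
    Vi: float   # mL/kg
    kc1: float  # 1/min
    kc12: float  # 1/min
    kc2: float  # 1/min
    kcl: float  # 1/min
    Si: float   # mL/(U*min)
    G0: float = 250.0   # zero-basal-insulin fasting glucose, mg/dL (level anchor)

    def __post_init__(self) -> None:
        rates = {k: getattr(self, k) for k in ("Sg", "p2", "kc1", "kc12", "kc2", "kcl")}
        for name, value in rates.items():
            if value <= 0:
                raise ParameterError(f"rate {name} must be > 0, got {value}")
        if self.Si < 0:
            raise ParameterError(f"Si must be >= 0, got {self.Si}")
        if not 120 < self.G0 < 600:
            raise ParameterError(f"G0 must be in (120, 600) mg/dL, got {self.G0}")
        if not 70 < self.Gb < 200:
            raise ParameterError(f"Gb must be in (70, 200) mg/dL, got {self.Gb}")
        if not 30 < self.BW < 200:
            raise ParameterError(f"BW must be in (30, 200) kg, got {self.BW}")
        if self.Vg <= 0 or self.Vi <= 0:
            raise ParameterError("distribution volumes must be > 0")


@dataclass(frozen=True)
class BasalPKParameters:
    """Long-acting (glargine-like) insulin pharmacokinetics.

    The dose splits at injection: a fraction ``precip_fraction`` precipitates
    and re-dissolves at rate ``ksp``; the rest enters the soluble depot
    directly and is absorbed to plasma at rate ``ka``. ``F`` is overall
    bioavailability.
    """

    F: float
    precip_fraction: float
    ksp: float  # 1/min
    ka: float   # 1/min

    def __post_init__(self) -> None:
        if not 0 < self.F <= 1:
            raise ParameterError(f"F must be in (0, 1], got {self.F}")
        if not 0 <= self.precip_fraction <= 1:
            raise ParameterError(f"precip_fraction must be in [0, 1], got {self.precip_fraction}")
        if self.ksp <= 0 or self.ka <= 0:
            raise ParameterError("ksp and ka must be > 0")


@dataclass(frozen=True)
class MealAbsorptionParameters:
    """Two-compartment (stomach/gut) carbohydrate absorption."""

    f: float     # bioavailability, dimensionless
    kq1: float   # stomach -> plasma, 1/min
    kq2: float   # gut -> plasma, 1/min
    kq12: float  # stomach -> gut, 1/min

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1.2:
            raise ParameterError(f"f must be in (0, 1.2], got {self.f}")
        if self.kq1 <= 0 or self.kq2 <= 0 or self.kq12 <= 0:
            raise ParameterError("meal absorption rates must be > 0")


@dataclass(frozen=True)
class TherapyParameters:
    """Insulin-dosing therapy parameters (500/1800 rules by default)."""

    TDI: float   # U/day
    CR: float    # g/U
    ISF: float   # mg/dL per U
    Gb: float    # mg/dL

    def __post_init__(self) -> None:
        if self.TDI <= 0:
            raise ParameterError(f"TDI must be > 0, got {self.TDI}")
        if self.CR <= 0 or self.ISF <= 0:
            raise ParameterError("CR and ISF must be > 0")

    @classmethod
    def from_tdi(cls, TDI: float, Gb: float = 110.0) -> "TherapyParameters":
        """Derive CR and ISF from TDI by the 500- and 1800-rules."""
        if TDI <= 0:
            raise ParameterError(f"TDI must be > 0, got {TDI}")
        return cls(TDI=TDI, CR=500.0 / TDI, ISF=1800.0 / TDI, Gb=Gb)


def population_from_config(cfg: Mapping[str, Any]) -> PopulationParameters:
    sec = dict(cfg["population"])
    sec.pop("source", None)
    return PopulationParameters(**sec)


def basal_pk_from_config(cfg: Mapping[str, Any]) -> BasalPKParameters:
    sec = dict(cfg["basal_pk"])
    sec.pop("source", None)
    return BasalPKParameters(**sec)


def meal_from_config(cfg: Mapping[str, Any], section: str = "meal") -> MealAbsorptionParameters:
    sec = dict(cfg[section])
    sec.pop("source", None)
    return MealAbsorptionParameters(**sec)


def replace(params, **changes):
    """``dataclasses.replace`` re-exported for parameter jittering."""
    return dataclasses.replace(params, **changes)
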