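"""SMBG-based basal titration baselines: control-to-range and control-to-
reference (iterative learning control).

Both consume fasting (pre-breakfast) fingerstick values collected over a
titration cycle and produce a new optimal dose that is then passed through
the same dead-zone/saturation update as the model-based algorithm.

Sign conventions: more insulin lowers glucose. The control-to-range rule
decreases the dose when any fasting value dips below G_min and increases it
when the cycle mean exceeds G_max. The ILC comparator filters the tracking
error (fasting mean minus target) and scales it by a per-subject DC gain of
3/BW U per mg/dL, increasing the dose when fasting glucose runs high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError


@dataclass(frozen=True)
class ControlToRangeConfig:
    """Range bounds and adjustment schedule of the heuristic rule."""

    G_min: float = 80.0
    G_max: float = 130.0
    decrement_frac: float = 0.10   # of the current dose
    decrement_floor: float = 1.0   # U
    increment_step: float = 0.5    # U per 20 mg/dL above G_max
    increment_per: float = 20.0    # mg/dL
    increment_min: float = 0.5
    increment_max: float = 5.0

    def __post_init__(self) -> None:
        if self.G_min >= self.G_max:
            raise ValueError("require G_min < G_max")


@dataclass
class ILCConfig:
    """Iterative-learning-control comparator configuration.

    The discrete filter F(q) is first order with pole ``filter_pole`` and a
    DC gain individualized to 3/BW (U per mg/dL).
    """

    gamma: float = 1.0
    G_target: float = 110.0
    filter_pole: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 <= self.filter_pole < 1:
            raise ValueError("filter pole must be in [0, 1)")


def titrate_control_to_range(smbg, B_c: float,
                             cfg: ControlToRangeConfig | None = None) -> float:
    """Control-to-range heuristic: the new optimal basal dose.

    Decrease by max(floor, 10% of B_c) if the cycle minimum is below G_min;
    increase by 0.5 U per started 20 mg/dL of mean excess over G_max
    (clipped to [0.5, 5] U); otherwise keep the dose.
    """
    cfg = cfg or ControlToRangeConfig()
    values = np.asarray(smbg, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one SMBG value")
    if np.min(values) < cfg.G_min:
        step = max(cfg.decrement_floor, cfg.decrement_frac * B_c)
        return B_c - step
    mean = float(np.mean(values))
    if mean > cfg.G_max:
        step = cfg.increment_step * np.ceil((mean - cfg.G_max) / cfg.increment_per)
        return B_c + float(np.clip(step, cfg.increment_min, cfg.increment_max))
    return B_c


@dataclass
class ILCState:
    """Filter memory carried across titration cycles."""

    u: float = 0.0


def titrate_ilc(smbg_mean: float, B_c: float, BW: float,
                cfg: ILCConfig | None = None, state: ILCState | None = None,
                ) -> tuple[float, ILCState]:
    """One ILC cycle: filtered fasting-error correction of the basal dose.

    ``smbg_mean`` is the cycle's mean pre-breakfast SMBG. The filtered
    correction u_c = p u_{c-1} + (1-p) (3/BW) (smbg_mean - G_target) has
    steady-state gain 3/BW U per mg/dL of sustained error. Returns
    (B_opt, updated state); the caller applies the shared dead-zone update.
    """
    cfg = cfg or ILCConfig()
    if BW <= 0:
        raise ParameterError("BW must be > 0")
    state = state or ILCState()
    error = float(smbg_mean) - cfg.G_target     # positive when running high
    gain = 3.0 / BW
    p = cfg.filter_pole
    u = p * state.u + (1.0 - p) * gain * error
    return B_c + cfg.gamma * u, ILCState(u=u)
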