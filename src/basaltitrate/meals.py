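"""Carbohydrate-input reconstruction from bolus records and glucose.

The titration algorithm does not require carbohydrate records. Meals are
reconstructed by inverting standard insulin dosing rules: a bolus U at
glucose G implies counted carbohydrates of roughly

    U_meal = max( CR * (U_bolus - (G - Gb)/ISF), 0 )      [grams]

with CR = 500/TDI (g covered per U) and ISF = 1800/TDI (mg/dL per U).
Reconstructed amounts are deliberately coarse: per-meal absorption
parameters remain free during model individualization, which absorbs meal
size errors.

Unbolused meals (snacks without insulin) are added by a slope-based
detector; the identification stage re-estimates their size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError, TherapyParameters


def reconstruct_meals(G: np.ndarray, U_bolus: np.ndarray,
                      therapy: TherapyParameters) -> np.ndarray:
    """Rebuild the carbohydrate input (grams) at bolus samples.

    Masked (NaN) glucose at a bolus sample contributes no correction term.
    The result is nonzero only where ``U_bolus`` is nonzero and clipped at 0.
    """
    G = np.asarray(G, float)
    U_bolus = np.asarray(U_bolus, float)
    if G.shape != U_bolus.shape:
        raise ValueError("G and U_bolus must share length")
    if therapy.TDI <= 0:
        raise ParameterError("TDI must be > 0")
    cr = 500.0 / therapy.TDI
    isf = 1800.0 / therapy.TDI
    correction = np.where(np.isnan(G), 0.0, (np.nan_to_num(G) - therapy.Gb) / isf)
    grams = np.maximum(cr * (U_bolus - correction), 0.0)
    grams[U_bolus == 0] = 0.0
    return grams


@dataclass(frozen=True)
class DetectorConfig:
    """Unbolused-meal detector thresholds (config keys, not physiology)."""

    slope_threshold: float = 1.5   # mg/dL/min, 30-min backward slope
    sustain_min: float = 20.0      # minutes above threshold to flag
    exclusion_min: float = 120.0   # post-bolus exclusion window, minutes
    slope_window_min: float = 30.0


def detect_unbolused_meals(G: np.ndarray, dt: float, U_bolus: np.ndarray,
                           cfg: DetectorConfig | None = None,
                           vg_bw: float = 112.0, f: float = 0.9) -> np.ndarray:
    """Heuristic detector for glucose rises without a recorded bolus.

    A detection fires when the 30-min backward CGM slope exceeds the
    threshold for at least ``sustain_min`` minutes, outside the post-bolus
    exclusion window. The impulse is placed at the onset of the rise and its
    size guess is rise amplitude x Vg*BW / f (coarse by design; the
    identification stage re-estimates absorption per meal).

    Returns an array (grams) aligned with G; empty days return all zeros.
    """
    if cfg is None:
        cfg = DetectorConfig()
    G = np.asarray(G, float)
    U_bolus = np.asarray(U_bolus, float)
    n = G.size
    out = np.zeros(n)
    w = max(1, int(round(cfg.slope_window_min / dt)))
    need = max(1, int(round(cfg.sustain_min / dt)))
    excl = int(round(cfg.exclusion_min / dt))

    # backward slope over the window, NaN-tolerant
    slope = np.full(n, np.nan)
    for k in range(w, n):
        a, b = G[k - w], G[k]
        if not (np.isnan(a) or np.isnan(b)):
            slope[k] = (b - a) / (w * dt)

    bolus_idx = np.flatnonzero(U_bolus > 0)
    excluded = np.zeros(n, dtype=bool)
    for i in bolus_idx:
        excluded[i:min(n, i + excl + 1)] = True

    hot = (slope > cfg.slope_threshold) & ~excluded
    k = 0
    while k < n:
        if not hot[k]:
            k += 1
            continue
        j = k
        while j < n and hot[j]:
            j += 1
        if j - k >= need:
            onset = max(0, k - w)               # slope window lags the rise onset
            peak = j
            while peak < n - 1 and not np.isnan(G[peak + 1]) and G[peak + 1] >= G[peak]:
                peak += 1
            g_on = G[onset] if not np.isnan(G[onset]) else G[k]
            amplitude = max(0.0, (G[peak] if not np.isnan(G[peak]) else g_on) - g_on)
            out[onset] += amplitude * vg_bw / f / 1000.0   # mg -> g
        k = j
    return out
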