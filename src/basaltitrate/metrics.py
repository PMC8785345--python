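"""Glycemic outcome metrics and trial summaries.

Boundary convention (consensus CGM-metrics usage): time in range counts
70 <= g <= 180 mg/dL inclusive, time below range g < 70, time above range
g > 180, so TBR + TIR + TAR partitions every sample exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class GlycemicMetrics:
    """Percent-time metrics plus moments for one glucose sample set."""

    tir_70_180: float
    tir_70_140: float
    tbr_70: float
    tbr_54: float
    tar_180: float
    tar_250: float
    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, g: np.ndarray) -> "GlycemicMetrics":
        g = np.asarray(g, float)
        g = g[~np.isnan(g)]
        if g.size == 0:
            raise ValueError("empty window")
        pct = lambda m: 100.0 * float(np.mean(m))  # noqa: E731
        return cls(tir_70_180=pct((g >= 70) & (g <= 180)),
                   tir_70_140=pct((g >= 70) & (g <= 140)),
                   tbr_70=pct(g < 70), tbr_54=pct(g < 54),
                   tar_180=pct(g > 180), tar_250=pct(g > 250),
                   mean=float(np.mean(g)), sd=float(np.std(g, ddof=1)) if g.size > 1 else 0.0,
                   n=int(g.size))


def glycemic_metrics(values: np.ndarray, times: np.ndarray | None = None,
                     window: tuple[float, float] | None = None,
                     night: tuple[float, float] = (0.0, 360.0),
                     ) -> dict[str, GlycemicMetrics]:
    """Overall and night-stratified metrics for a gridded glucose trace.

    ``times`` are absolute minutes (used for windowing and the night clock
    mask); without them the whole trace is 'overall' and night requires
    times. Raises on an empty window.
    """
    values = np.asarray(values, float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    times = np.asarray(times, float)
    sel = np.ones(values.size, dtype=bool)
    if window is not None:
        sel &= (times >= window[0]) & (times < window[1])
    if not np.any(sel):
        raise ValueError("empty window")
    out = {"overall": GlycemicMetrics.from_values(values[sel])}
    clock = times % MINUTES_PER_DAY
    nsel = sel & (clock >= night[0]) & (clock < night[1])
    if np.any(nsel):
        out["night"] = GlycemicMetrics.from_values(values[nsel])
    return out


# ---------------------------------------------------------------------------
# Trial-level summaries
# ---------------------------------------------------------------------------

_METRIC_FIELDS = ("tir_70_180", "tir_70_140", "tbr_70", "tbr_54",
                  "tar_180", "tar_250", "mean", "sd")


def _subject_period_metrics(rec, day_lo: int, day_hi: int, dt: float,
                            which: str = "cgm") -> dict[str, float]:
    if which == "cgm":
        vals = rec.cgm[day_lo:day_hi].ravel()
        step = dt
    else:
        vals = rec.truth[day_lo:day_hi].ravel()
        step = 1.0
    times = day_lo * MINUTES_PER_DAY + step * np.arange(vals.size)
    m = glycemic_metrics(vals, times)
    row = {f: getattr(m["overall"], f) for f in _METRIC_FIELDS}
    row.update({f"night_{f}": getattr(m["night"], f) for f in _METRIC_FIELDS})
    row["basal_U"] = float(np.mean(rec.doses_by_day[day_lo:day_hi]))
    bol = [u for t, u, *_ in rec.boluses if day_lo * MINUTES_PER_DAY <= t < day_hi * MINUTES_PER_DAY]
    row["bolus_U"] = float(np.sum(bol) / (day_hi - day_lo))
    row["total_U"] = row["basal_U"] + row["bolus_U"]
    row["smbg_prebreakfast"] = float(np.mean(rec.smbg[day_lo:day_hi]))
    return row


def summarize_trial(result, period: int = 15, baseline_days: int = 0,
                    which: str = "cgm") -> pd.DataFrame:
    """Cohort mean and sd of outcome metrics per consecutive period.

    The first ``baseline_days`` days form the 'baseline' row; the remaining
    days must split evenly into ``period``-day blocks. Change-from-baseline
    columns carry a normal-approximation 95% CI of the paired per-subject
    change (only when a baseline is present).
    """
    days = result.days
    if (days - baseline_days) % period != 0:
        raise ValueError("period must divide the post-baseline trial length")
    dt = result.scenario.dt
    blocks: list[tuple[str, int, int]] = []
    if baseline_days:
        blocks.append(("baseline", 0, baseline_days))
    for i, lo in enumerate(range(baseline_days, days, period)):
        blocks.append((f"days {lo + 1}-{lo + period}", lo, lo + period))

    per_subject = {label: pd.DataFrame([_subject_period_metrics(r, lo, hi, dt, which)
                                        for r in result.records])
                   for label, lo, hi in blocks}
    rows = []
    base = per_subject.get("baseline")
    for label, lo, hi in blocks:
        df = per_subject[label]
        for col in df.columns:
            entry = {"period": label, "metric": col,
                     "mean": df[col].mean(), "sd": df[col].std(ddof=1)}
            if base is not None:
                delta = df[col] - base[col]
                n = len(delta)
                half = 1.96 * delta.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
                entry.update(change=delta.mean(), ci_lo=delta.mean() - half,
                             ci_hi=delta.mean() + half)
            rows.append(entry)
    return pd.DataFrame(rows)


def dose_deviation_summary(result) -> pd.DataFrame:
    """Final-15-day basal dose deviation from each subject's steady-state
    requirement, stratified by the sign of the initial alteration."""
    rows = []
    for rec in result.records:
        final = float(np.mean(rec.doses_by_day[-15:]))
        dev_u = final - rec.subject.Ubasal_ss
        rows.append({"group": "higher" if rec.altered_up else "lower",
                     "deviation_U": dev_u,
                     "deviation_pct": 100.0 * dev_u / rec.subject.Ubasal_ss})
    df = pd.DataFrame(rows)
    return df.groupby("group").agg(n=("deviation_U", "size"),
                                   mean_U=("deviation_U", "mean"),
                                   sd_U=("deviation_U", "std"),
                                   mean_pct=("deviation_pct", "mean"),
                                   sd_pct=("deviation_pct", "std"))


def carb_sensitivity_report(arm_a, arm_b) -> dict:
    """Absolute per-cycle differences in the optimal dose between paired arms
    (carbohydrates reconstructed vs counted).

    Returns mean/sd/min/max of |B_opt difference| aggregated two ways:
    averaged per subject (over that subject's cycles) and averaged per
    change (over subjects at each cycle).
    """
    if not arm_a.paired_with(arm_b):
        raise ValueError("arms are not paired (seed/days/cohort differ)")
    # per-day optimal doses (unrounded) averaged within each titration change
    diffs = np.array([[float(np.mean(np.abs(np.subtract(da, db))))
                       for da, db in zip(ra.cycle_perday, rb.cycle_perday)]
                      for ra, rb in zip(arm_a.records, arm_b.records)])  # (subj, cycles)

    def stats(x):
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "min": float(np.min(x)), "max": float(np.max(x))}

    return {"per_subject": stats(diffs.mean(axis=1)),
            "per_change": stats(diffs.mean(axis=0)),
            "overall_mean": float(diffs.mean())}


def cycles_to_deadzone(result, tol: float = 0.5) -> np.ndarray:
    """First titration cycle (1-based) at which each subject's dose enters
    the dead zone around its true steady-state requirement; inf if never."""
    out = np.full(len(result.records), np.inf)
    for i, rec in enumerate(result.records):
        target = rec.subject.Ubasal_ss
        for c, d in enumerate(rec.cycle_doses, start=1):
            if abs(d - target) < tol:
                out[i] = c
                break
    return out


def final_tir(result, last_days: int = 15, which: str = "cgm",
              lo: float = 70.0, hi: float = 180.0) -> np.ndarray:
    """Per-subject overall time in [lo, hi] over the final days, percent."""
    vals = []
    for rec in result.records:
        g = (rec.cgm if which == "cgm" else rec.truth)[-last_days:].ravel()
        vals.append(100.0 * float(np.mean((g >= lo) & (g <= hi))))
    return np.asarray(vals)


def final_smbg_mean(result, last_days: int = 15) -> float:
    """Cohort mean pre-breakfast SMBG over the final days, mg/dL."""
    return float(np.mean([np.mean(rec.smbg[-last_days:]) for rec in result.records]))
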