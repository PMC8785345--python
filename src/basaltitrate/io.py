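"""Typed containers for glucose and dose records, CSV readers/writers, and
resampling onto the fixed time grid the titration algorithm assumes.

Conventions
-----------
* Timestamps are minutes from local midnight of day 0 (the date of the
  earliest record, or an explicit reference). Day boundaries fall at 00:00
  and all windows are half-open ``[t_a, t_b)``.
* Invalid glucose samples (outside (10, 1000) mg/dL) are kept but flagged,
  and become masked (NaN) grid samples; they are never interpolated.
* Duplicate timestamps keep the last record (pens resend corrected records).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GLUCOSE_VALID_RANGE = (10.0, 1000.0)
MINUTES_PER_DAY = 1440.0


class ParseError(ValueError):
    """A CSV row could not be parsed; the message names the line number."""


@dataclass
class GlucoseSeries:
    """A time-stamped glucose record (CGM trace or SMBG fingersticks)."""

    timestamps: np.ndarray          # minutes since reference midnight
    values: np.ndarray              # mg/dL
    source: str = "cgm"             # {"cgm", "smbg"}
    t_ref: pd.Timestamp | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.source not in ("cgm", "smbg"):
            raise ValueError(f"unknown glucose source {self.source!r}")
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.valid is None:
            lo, hi = GLUCOSE_VALID_RANGE
            self.valid = (self.values > lo) & (self.values < hi)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class DoseEvents:
    """Time-stamped insulin doses from a smart-pen log."""

    timestamps: np.ndarray  # minutes since reference midnight
    doses: np.ndarray       # U
    kinds: np.ndarray       # {"basal", "bolus"} per event
    t_ref: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if not (self.timestamps.shape == self.doses.shape == self.kinds.shape):
            raise ValueError("timestamps, doses and kinds must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        bad = set(np.unique(self.kinds)) - {"basal", "bolus"}
        if bad:
            raise ValueError(f"unknown dose kinds {sorted(bad)}")
        basal_days = (self.timestamps[self.kinds == "basal"] // MINUTES_PER_DAY).astype(int)
        if basal_days.size:
            _, counts = np.unique(basal_days, return_counts=True)
            if np.any(counts > 2):
                raise ValueError("basal doses must occur at most twice per calendar day")

    def __len__(self) -> int:
        return self.timestamps.size

    def select(self, kind: str) -> "DoseEvents":
        m = self.kinds == kind
        return DoseEvents(self.timestamps[m], self.doses[m], self.kinds[m], self.t_ref)


@dataclass
class DataBundle:
    """The record D = {G, U_basal, U_bolus} (+ reconstructed U_meal) on a
    fixed grid: the titration algorithm's sole patient input.

    ``G`` is NaN where no valid glucose sample fell within dt/2 of the grid
    point. Impulse arrays are zero except at event samples; ``U_meal`` is in
    grams, doses in U.
    """

    G: np.ndarray
    U_basal: np.ndarray
    U_bolus: np.ndarray
    U_meal: np.ndarray
    dt: float           # minutes
    t_start: float      # minutes since reference midnight (clock = t_start % 1440)
    t_ref: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        for name in ("G", "U_basal", "U_bolus", "U_meal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.G.size
        if not all(getattr(self, a).size == n for a in ("U_basal", "U_bolus", "U_meal")):
            raise ValueError("all bundle arrays must share length n")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n(self) -> int:
        return self.G.size

    @property
    def times(self) -> np.ndarray:
        """Absolute grid times, minutes since reference midnight."""
        return self.t_start + self.dt * np.arange(self.n)

    @property
    def mask(self) -> np.ndarray:
        """True where the glucose sample is valid."""
        return ~np.isnan(self.G)


def _reference_midnight(ts: pd.Series, reference: pd.Timestamp | None) -> pd.Timestamp:
    if reference is not None:
        return pd.Timestamp(reference).normalize()
    return ts.min().normalize()


def _minutes(ts: pd.Series, ref: pd.Timestamp) -> np.ndarray:
    return ((ts - ref).dt.total_seconds() / 60.0).to_numpy()


def load_series(path, schema: str, reference=None):
    """Read a CGM or pen CSV file.

    ``schema='cgm'`` expects columns (timestamp, glucose_mgdl);
    ``schema='pen'`` expects (timestamp, units, kind) with kind in
    {basal, bolus}. Rows are sorted by time and duplicate timestamps keep
    the last record. An empty file yields an empty container.
    """
    if schema not in ("cgm", "pen"):
        raise ValueError(f"unknown schema {schema!r}")
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return _empty(schema)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                ts = pd.Timestamp(row[0].strip())
                if schema == "cgm":
                    value = float(row[1])
                    rows.append((ts, value))
                else:
                    units = float(row[1])
                    kind = row[2].strip().lower()
                    if units < 0:
                        raise ValueError(f"negative dose {units}")
                    if kind not in ("basal", "bolus"):
                        raise ValueError(f"unknown kind {kind!r}")
                    rows.append((ts, units, kind))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        return _empty(schema)
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(0, kind="stable").drop_duplicates(subset=0, keep="last")
    ref = _reference_midnight(frame[0], reference)
    t = _minutes(frame[0], ref)
    if schema == "cgm":
        return GlucoseSeries(t, frame[1].to_numpy(float), source="cgm", t_ref=ref)
    return DoseEvents(t, frame[1].to_numpy(float), frame[2].to_numpy(object), t_ref=ref)


def _empty(schema: str):
    if schema == "cgm":
        return GlucoseSeries(np.empty(0), np.empty(0), source="cgm")
    return DoseEvents(np.empty(0), np.empty(0), np.empty(0, dtype=object))


def write_series(obj, path) -> None:
    """Write a container back to CSV in the same schema ``load_series`` reads."""
    ref = obj.t_ref if obj.t_ref is not None else pd.Timestamp("2000-01-01")
    stamps = ref + pd.to_timedelta(obj.timestamps, unit="m")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if isinstance(obj, GlucoseSeries):
            writer.writerow(["timestamp", "glucose_mgdl"])
            for ts, v in zip(stamps, obj.values):
                writer.writerow([ts.isoformat(), f"{v:g}"])
        elif isinstance(obj, DoseEvents):
            writer.writerow(["timestamp", "units", "kind"])
            for ts, d, k in zip(stamps, obj.doses, obj.kinds):
                writer.writerow([ts.isoformat(), f"{d:g}", k])
        else:
            raise TypeError(f"cannot write {type(obj).__name__}")


def _nearest_grid_values(grid: np.ndarray, t: np.ndarray, v: np.ndarray, half: float) -> np.ndarray:
    """Nearest-in-time sample for each grid point, NaN beyond ``half``."""
    out = np.full(grid.size, np.nan)
    if t.size == 0:
        return out
    idx = np.searchsorted(t, grid)
    left = np.clip(idx - 1, 0, t.size - 1)
    right = np.clip(idx, 0, t.size - 1)
    dl = np.abs(grid - t[left])
    dr = np.abs(t[right] - grid)
    pick = np.where(dl <= dr, left, right)
    dist = np.minimum(dl, dr)
    ok = dist <= half
    out[ok] = v[pick[ok]]
    return out


def resample_bundle(glucose: GlucoseSeries, doses: DoseEvents, dt: float,
                    window: tuple[float, float]) -> DataBundle:
    """Grid glucose and dose records onto a fixed-dt half-open window.

    Each grid sample takes the nearest-in-time valid CGM value within dt/2
    (else it is masked). Each dose becomes an impulse at its nearest grid
    sample; the total dose is conserved exactly. Raises ``ValueError`` if the
    window contains no glucose at all.
    """
    t_a, t_b = float(window[0]), float(window[1])
    length = t_b - t_a
    if length <= 0:
        raise ValueError("window must have positive length")
    n = length / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError("dt must divide the window length")
    n = int(round(n))
    grid = t_a + dt * np.arange(n)

    gm = (glucose.timestamps >= t_a) & (glucose.timestamps < t_b) & glucose.valid
    if not np.any(gm):
        raise ValueError("empty record: no valid glucose in window")
    G = _nearest_grid_values(grid, glucose.timestamps[gm], glucose.values[gm], dt / 2.0)

    arrays = {"basal": np.zeros(n), "bolus": np.zeros(n)}
    dm = (doses.timestamps >= t_a) & (doses.timestamps < t_b)
    for t, d, k in zip(doses.timestamps[dm], doses.doses[dm], doses.kinds[dm]):
        i = int(np.clip(round((t - t_a) / dt), 0, n - 1))
        arrays[k][i] += d

    return DataBundle(G=G, U_basal=arrays["basal"], U_bolus=arrays["bolus"],
                      U_meal=np.zeros(n), dt=float(dt), t_start=t_a,
                      t_ref=glucose.t_ref)
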