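"""Parsing, regularization and quality checks for wearable EMA stress exports.

Wrist-worn trackers report a heart-rate-variability-derived stress index in
[0, 100] once per epoch (3 minutes by default).  Device exports are CSV with
one row per epoch; a stress value of -1 marks an epoch with insufficient data
and -2 an epoch the wearer was physically active.  Rows for whole epochs can
additionally be absent from the export.  This module turns such files into a
:class:`StressSeries` on a strictly regular epoch grid and computes wear-time
suitability.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CODE_OBSERVED",
    "CODE_INSUFFICIENT",
    "CODE_ACTIVITY",
    "CODE_ABSENT",
    "CODE_MISSING",
    "StressSeries",
    "WearReport",
    "parse_stress_csv",
    "write_stress_csv",
    "regularize_grid",
    "wear_report",
    "categorize_stress",
    "modeling_view",
    "to_excel_serial",
]

# Per-slot status codes.  0 is the only code with an observed stress value.
CODE_OBSERVED = 0
CODE_INSUFFICIENT = 1  # device recorded -1: not enough data in the epoch
CODE_ACTIVITY = 2      # device recorded -2: physical activity
CODE_ABSENT = 3        # no row in the export at all
CODE_MISSING = 4       # any of the above, collapsed for modelling

_CODE_NAMES = {
    CODE_OBSERVED: "observed",
    CODE_INSUFFICIENT: "insufficient",
    CODE_ACTIVITY: "activity",
    CODE_ABSENT: "absent_row",
    CODE_MISSING: "missing",
}

#: Seconds per day / Excel day-number of the Unix epoch (1970-01-01).
_EXCEL_EPOCH_OFFSET_DAYS = 25569.0


def to_excel_serial(ts: pd.Timestamp) -> float:
    """Convert a UTC timestamp to an Excel date-time serial number.

    Days since 1899-12-30, fractional part = time of day.  No leap-second
    handling; intended only as an export convenience.
    """
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.timestamp() / 86400.0 + _EXCEL_EPOCH_OFFSET_DAYS


@dataclasses.dataclass
class StressSeries:
    """A patient's stress series on a (possibly gapped) epoch grid.

    ``slots`` holds the grid offset of each entry relative to ``epoch_start``
    in units of ``epoch_minutes``.  A regularized series has
    ``slots == arange(n)``; a freshly parsed export may have gaps.

    Invariants: ``values[k]`` is finite iff ``codes[k] == CODE_OBSERVED``;
    observed values lie in [0, 100]; ``slots`` is strictly increasing and
    starts at 0.
    """

    patient_id: str
    epoch_start: pd.Timestamp
    values: np.ndarray
    codes: np.ndarray
    epoch_minutes: int = 3
    slots: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.slots is None:
            self.slots = np.arange(self.values.size, dtype=np.int64)
        else:
            self.slots = np.asarray(self.slots, dtype=np.int64)
        if self.values.shape != self.codes.shape or self.values.shape != self.slots.shape:
            raise ValueError("values, codes and slots must have equal length")
        if self.values.size == 0:
            raise ValueError("empty stress series")
        self.epoch_start = pd.Timestamp(self.epoch_start)
        if self.epoch_start.tzinfo is None:
            self.epoch_start = self.epoch_start.tz_localize("UTC")
        if self.slots[0] != 0 or np.any(np.diff(self.slots) <= 0):
            raise ValueError("slots must start at 0 and be strictly increasing")
        obs = self.codes == CODE_OBSERVED
        if np.any(np.isfinite(self.values) != obs):
            raise ValueError("values present exactly where code is 'observed'")
        if obs.any():
            v = self.values[obs]
            if v.min() < 0 or v.max() > 100:
                raise ValueError("observed stress values must lie in [0, 100]")

    # -- basic views ---------------------------------------------------

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def is_regular(self) -> bool:
        return bool(self.slots[-1] == self.values.size - 1)

    @property
    def n_slots(self) -> int:
        """Number of grid slots spanned (inclusive of gaps)."""
        return int(self.slots[-1]) + 1

    def timestamps(self) -> pd.DatetimeIndex:
        return self.epoch_start + pd.to_timedelta(
            self.slots * self.epoch_minutes, unit="m"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps(),
                "slot": self.slots,
                "stress": self.values,
                "code": [_CODE_NAMES[int(c)] for c in self.codes],
            }
        )

    def copy(self) -> "StressSeries":
        return StressSeries(
            patient_id=self.patient_id,
            epoch_start=self.epoch_start,
            values=self.values.copy(),
            codes=self.codes.copy(),
            epoch_minutes=self.epoch_minutes,
            slots=self.slots.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StressSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.epoch_start == other.epoch_start
            and self.epoch_minutes == other.epoch_minutes
            and np.array_equal(self.slots, other.slots)
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclasses.dataclass(frozen=True)
class WearReport:
    """Wear-time accounting for a regularized series.

    A slot counts as "worn" if the device produced any record for it
    (an observed value, a -1 or a -2); only wholly absent rows count
    against wear time.  Suitability requires wear_fraction strictly
    above 0.5.
    """

    n_slots: int
    n_observed: int
    n_insufficient: int
    n_activity: int
    n_absent: int
    wear_fraction: float
    suitable: bool

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _parse_timestamps(raw: pd.Series, timezone_policy: str) -> pd.DatetimeIndex:
    """Auto-detect Unix-epoch-seconds vs ISO-8601 timestamp columns."""
    if timezone_policy not in {"utc", "naive_is_utc"}:
        raise ValueError(f"unknown timezone_policy {timezone_policy!r}")
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return pd.DatetimeIndex(pd.to_datetime(numeric, unit="s", utc=True))
    try:
        ts = pd.to_datetime(raw, utc=True, format="ISO8601")
    except (ValueError, TypeError):
        bad = None
        for i, val in enumerate(raw):
            try:
                pd.to_datetime(val, utc=True)
            except (ValueError, TypeError):
                bad = (i, val)
                break
        if bad is not None:
            raise ValueError(
                f"unparseable timestamp at data row {bad[0]}: {bad[1]!r}"
            ) from None
        ts = pd.to_datetime(raw, utc=True)
    if ts.isna().any():
        i = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(f"unparseable timestamp at data row {i}: {raw.iloc[i]!r}")
    return pd.DatetimeIndex(ts)


def _slots_from_timestamps(
    ts: pd.DatetimeIndex, epoch_minutes: int
) -> np.ndarray:
    offsets = (ts - ts[0]).total_seconds()
    step = epoch_minutes * 60.0
    slots = offsets / step
    rounded = np.rint(slots)
    misaligned = np.abs(slots - rounded) > 1e-9
    if misaligned.any():
        i = int(np.flatnonzero(misaligned)[0])
        raise ValueError(
            f"timestamp at data row {i} ({ts[i].isoformat()}) is not aligned "
            f"to the {epoch_minutes}-min epoch grid"
        )
    return rounded.astype(np.int64)


def parse_stress_csv(
    path: str | Path,
    timezone_policy: str = "utc",
    *,
    epoch_minutes: int = 3,
    column_map: dict[str, str] | None = None,
    patient_id: str | None = None,
) -> StressSeries:
    """Read a device stress export into a :class:`StressSeries`.

    The file must have a header naming a timestamp column and a stress
    column (``timestamp`` and ``stress`` by default; override with
    ``column_map={"timestamp": ..., "stress": ...}``).  Timestamps are
    either ISO-8601 (interpreted as UTC) or Unix epoch seconds,
    auto-detected.  Stress values must be in [0, 100] or one of the
    missing codes -1 (insufficient data) / -2 (physical activity).

    Returns the series on the raw, possibly gapped, grid — use
    :func:`regularize_grid` to fill absent rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = {"timestamp": "timestamp", "stress": "stress"}
    if column_map:
        cols.update(column_map)
    for role, name in cols.items():
        if name not in df.columns:
            raise ValueError(f"{path}: missing {role} column {name!r}")
    ts = _parse_timestamps(df[cols["timestamp"]], timezone_policy)
    order = np.argsort(ts.values, kind="stable")
    ts = ts[order]
    stress = pd.to_numeric(df[cols["stress"]].iloc[order], errors="raise").to_numpy(
        dtype=float
    )
    if ts.duplicated().any():
        dup = ts[ts.duplicated()][0]
        raise ValueError(f"{path}: duplicate timestamp {dup.isoformat()}")

    valid = ((stress >= 0) & (stress <= 100)) | (stress == -1) | (stress == -2)
    if not valid.all():
        i = int(np.flatnonzero(~valid)[0])
        raise ValueError(
            f"{path}: stress value {stress[i]!r} at data row {i} outside "
            "[0, 100] and not a missing code (-1/-2)"
        )
    codes = np.full(stress.size, CODE_OBSERVED, dtype=np.int8)
    codes[stress == -1] = CODE_INSUFFICIENT
    codes[stress == -2] = CODE_ACTIVITY
    values = stress.copy()
    values[codes != CODE_OBSERVED] = np.nan

    slots = _slots_from_timestamps(ts, epoch_minutes)
    return StressSeries(
        patient_id=patient_id or path.stem,
        epoch_start=ts[0],
        values=values,
        codes=codes,
        epoch_minutes=epoch_minutes,
        slots=slots,
    )


def write_stress_csv(series: StressSeries, path: str | Path) -> Path:
    """Write a series back to the export dialect (``timestamp,stress``).

    Slots coded ``absent_row`` produce no row, mirroring real exports.
    """
    path = Path(path)
    keep = series.codes != CODE_ABSENT
    ts = series.timestamps()[keep]
    vals = series.values[keep].copy()
    codes = series.codes[keep]
    out = vals
    out[codes == CODE_INSUFFICIENT] = -1
    out[codes == CODE_ACTIVITY] = -2
    out[codes == CODE_MISSING] = -1  # collapsed views export as insufficient
    df = pd.DataFrame(
        {
            "timestamp": [t.strftime("%Y-%m-%dT%H:%M:%SZ") for t in ts],
            "stress": [int(v) if float(v).is_integer() else v for v in out],
        }
    )
    df.to_csv(path, index=False)
    return path


def regularize_grid(series: StressSeries) -> StressSeries:
    """Fill the epoch grid so every slot between first and last exists.

    Slots with no source row are coded ``absent_row``.  Idempotent on an
    already-regular series.
    """
    if series.is_regular:
        return series.copy()
    n = series.n_slots
    values = np.full(n, np.nan)
    codes = np.full(n, CODE_ABSENT, dtype=np.int8)
    values[series.slots] = series.values
    codes[series.slots] = series.codes
    return StressSeries(
        patient_id=series.patient_id,
        epoch_start=series.epoch_start,
        values=values,
        codes=codes,
        epoch_minutes=series.epoch_minutes,
    )


def wear_report(series: StressSeries) -> WearReport:
    """Count slot statuses and decide wear-time suitability (> 50% strict)."""
    if len(series) == 0:
        raise ValueError("empty series")
    if not series.is_regular:
        raise ValueError("wear_report requires a regularized grid")
    counts = np.bincount(series.codes, minlength=5)
    n = len(series)
    n_obs = int(counts[CODE_OBSERVED])
    n_ins = int(counts[CODE_INSUFFICIENT])
    n_act = int(counts[CODE_ACTIVITY])
    n_abs = int(counts[CODE_ABSENT] + counts[CODE_MISSING])
    worn = (n_obs + n_ins + n_act) / n
    return WearReport(
        n_slots=n,
        n_observed=n_obs,
        n_insufficient=n_ins,
        n_activity=n_act,
        n_absent=n_abs,
        wear_fraction=worn,
        suitable=worn > 0.5,
    )


_CATEGORY_EDGES = ((25, "rest"), (50, "low"), (75, "medium"), (100, "high"))


def categorize_stress(value: float) -> str:
    """Map a stress value to the device's bands.

    0-25 rest, 26-50 low, 51-75 medium, 76-100 high (integer band edges
    inclusive).
    """
    if value is None or not np.isfinite(value):
        raise ValueError("cannot categorize a missing stress value")
    if value < 0 or value > 100:
        raise ValueError(f"stress value {value} outside [0, 100]")
    for edge, name in _CATEGORY_EDGES:
        if value <= edge:
            return name
    raise AssertionError("unreachable")


def modeling_view(series: StressSeries) -> StressSeries:
    """Collapse all missing categories to a single 'missing' code.

    Observed values are untouched and nothing is imputed: the model uses
    complete adjacent lag pairs only, because imputing would fabricate the
    autocorrelation being estimated.
    """
    if not series.is_regular:
        raise ValueError("modeling_view requires a regularized grid")
    codes = series.codes.copy()
    codes[codes != CODE_OBSERVED] = CODE_MISSING
    return StressSeries(
        patient_id=series.patient_id,
        epoch_start=series.epoch_start,
        values=series.values.copy(),
        codes=codes,
        epoch_minutes=series.epoch_minutes,
    )
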