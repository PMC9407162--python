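"""Reading sensor streams, temporal-slice filtering, and coverage checks.

Streams are plain delimited-text files, one per participant per sensor, laid
out as ``<cohort>/<participant_id>/<sensor>.csv``. Timestamps are naive local
datetimes. A temporal slice is a (time-of-day epoch x day-of-week set) filter;
five epochs crossed with three day sets give the 15 slices used throughout.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    CALL_TYPES,
    DAYSETS,
    EPOCH_ORDER,
    EPOCHS,
    EVENT_SENSORS,
    EXPECTED_SAMPLES_PER_DAY,
    SAMPLED_SENSORS,
    SENSORS,
    SLEEP_STATUSES,
    STREAM_COLUMNS,
)


class StreamFormatError(ValueError):
    """A stream file is missing mandatory columns or is otherwise unreadable."""


@dataclasses.dataclass(frozen=True, order=True)
class TemporalSlice:
    """One of the 15 (epoch, dayset) filters.

    Epoch windows are half-open: night [00:00, 06:00), morning [06:00, 12:00),
    afternoon [12:00, 18:00), evening [18:00, 24:00). Weekdays are Monday
    through Friday.
    """

    epoch: str
    dayset: str

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.dayset not in DAYSETS:
            raise ValueError(f"unknown dayset {self.dayset!r}")

    @property
    def name(self) -> str:
        return f"{self.epoch}.{self.dayset}"

    @classmethod
    def all_slices(cls) -> list["TemporalSlice"]:
        """The 15 slices in canonical (epoch-major) order."""
        return [cls(e, d) for e in EPOCH_ORDER for d in DAYSETS]


ALL_SLICES: tuple[TemporalSlice, ...] = tuple(TemporalSlice.all_slices())


def epoch_mask(timestamps: pd.Series, epoch: str) -> np.ndarray:
    """Boolean mask of records whose local time falls in the epoch window."""
    lo, hi = EPOCHS[epoch]
    if (lo, hi) == (0, 24):
        return np.ones(len(timestamps), dtype=bool)
    hours = timestamps.dt.hour.to_numpy()
    return (hours >= lo) & (hours < hi)


def dayset_mask(dates, dayset: str) -> np.ndarray:
    """Boolean mask of records whose calendar day belongs to the dayset."""
    if dayset == "all_days":
        return np.ones(len(dates), dtype=bool)
    dow = pd.DatetimeIndex(dates).dayofweek.to_numpy()
    if dayset == "weekdays":
        return dow < 5
    return dow >= 5


def slice_filter(stream: pd.DataFrame, sl: TemporalSlice) -> pd.DataFrame:
    """Keep records whose local time is in the slice's epoch window and whose
    calendar day is in its dayset. ``(all_day, all_days)`` is the identity."""
    if sl.epoch == "all_day" and sl.dayset == "all_days":
        return stream
    ts = stream["timestamp"]
    mask = epoch_mask(ts, sl.epoch) & dayset_mask(ts.dt.normalize(), sl.dayset)
    return stream.loc[mask]


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_VALIDATORS = {
    "calls": lambda df: df["call_type"].isin(CALL_TYPES)
    & (pd.to_numeric(df["duration_s"], errors="coerce") >= 0),
    "screen": lambda df: df["event"].isin(("on", "off", "lock", "unlock")),
    "location": lambda df: pd.to_numeric(df["lat"], errors="coerce").between(-90, 90)
    & pd.to_numeric(df["lon"], errors="coerce").between(-180, 180),
    "steps": lambda df: pd.to_numeric(df["steps"], errors="coerce") >= 0,
    "sleep": lambda df: df["status"].isin(SLEEP_STATUSES),
    "heart": lambda df: pd.to_numeric(df["bpm"], errors="coerce").between(
        0, 300, inclusive="neither"
    ),
}

_NUMERIC_COLS = {
    "calls": ["duration_s"],
    "location": ["lat", "lon"],
    "steps": ["steps"],
    "heart": ["bpm"],
}


def load_stream(path: Path, sensor: str) -> tuple[pd.DataFrame, int]:
    """Load one sensor file.

    Returns the cleaned stream (sorted by timestamp, duplicates on timestamp
    deduplicated keeping the first record, invalid rows dropped) and the count
    of malformed rows that were removed.

    Raises :class:`StreamFormatError` if a mandatory column is absent.
    """
    cols = STREAM_COLUMNS[sensor]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing column(s) {missing}")
    df = df[cols]
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    ok = ts.notna() & _VALIDATORS[sensor](df)
    n_bad = int((~ok).sum())
    df = df.loc[ok].copy()
    df["timestamp"] = ts.loc[ok]
    for c in _NUMERIC_COLS.get(sensor, []):
        df[c] = pd.to_numeric(df[c])
    df = df.sort_values("timestamp", kind="stable")
    df = df.drop_duplicates(subset="timestamp", keep="first").reset_index(drop=True)
    return df, n_bad


def load_streams(cohort_dir: str | Path) -> tuple[dict[str, dict[str, pd.DataFrame]], pd.DataFrame]:
    """Load every participant's sensor streams from a cohort directory.

    Returns ``(streams, report)`` where ``streams[participant][sensor]`` is a
    cleaned DataFrame and ``report`` counts records and malformed rows per
    (participant, sensor). Missing sensor files yield empty streams.
    """
    cohort_dir = Path(cohort_dir)
    streams: dict[str, dict[str, pd.DataFrame]] = {}
    rows = []
    for pdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        pid = pdir.name
        streams[pid] = {}
        for sensor in SENSORS:
            path = pdir / f"{sensor}.csv"
            if path.exists():
                df, n_bad = load_stream(path, sensor)
            else:
                df = pd.DataFrame({c: pd.Series(dtype=object) for c in STREAM_COLUMNS[sensor]})
                df["timestamp"] = pd.to_datetime(df["timestamp"])
                n_bad = 0
            streams[pid][sensor] = df
            rows.append({"participant_id": pid, "sensor": sensor,
                         "n_records": len(df), "n_malformed": n_bad})
    report = pd.DataFrame(rows)
    return streams, report


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoverageThresholds:
    """Concrete missing-data policy.

    A sampled sensor-day is valid when at least ``min_day_fraction`` of the
    expected samples for that day were observed. Event-stream days (calls,
    screen) are valid when any screen event exists that day — a phone-alive
    proxy. A participant is eligible when at least ``min_valid_days`` valid
    days exist in each study period for at least one sensor; a sensor's
    features are usable for a participant when that sensor has at least
    ``min_valid_days`` valid days in both periods.
    """

    min_day_fraction: float = 0.5
    min_valid_days: int = 7
    expected_per_day: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(EXPECTED_SAMPLES_PER_DAY)
    )


@dataclasses.dataclass
class CoverageReport:
    """Valid-day bookkeeping for one cohort."""

    #: rows: participant_id, sensor, period, n_valid_days, expected_fraction, usable
    table: pd.DataFrame
    #: participant_id -> bool
    eligible: dict[str, bool]
    #: (participant_id, sensor) -> bool (enough valid days in both periods)
    sensor_usable: dict[tuple[str, str], bool]
    #: (participant_id, sensor) -> set of valid calendar dates
    valid_days: dict[tuple[str, str], set]


def valid_days_for_sensor(
    streams: Mapping[str, pd.DataFrame],
    sensor: str,
    thresholds: CoverageThresholds,
) -> set:
    """Set of calendar dates on which ``sensor`` has a valid day."""
    if sensor in SAMPLED_SENSORS:
        df = streams[sensor]
        if df.empty:
            return set()
        counts = df["timestamp"].dt.normalize().value_counts()
        need = thresholds.min_day_fraction * thresholds.expected_per_day[sensor]
        return {d.date() for d, c in counts.items() if c >= need}
    # event sensors: phone-alive proxy from the screen stream
    screen = streams.get("screen")
    if screen is None or screen.empty:
        return set()
    return {d.date() for d in screen["timestamp"].dt.normalize().unique()}


def coverage(
    all_streams: Mapping[str, Mapping[str, pd.DataFrame]],
    period_bounds: tuple[datetime.date, datetime.date, datetime.date],
    thresholds: CoverageThresholds | None = None,
) -> CoverageReport:
    """Compute valid days, per-sensor usability, and participant eligibility.

    ``period_bounds`` is (study_start, period_boundary, study_end); the
    pre-period is [start, boundary) and the stay-at-home period is
    [boundary, end), both half-open.
    """
    thresholds = thresholds or CoverageThresholds()
    start, boundary, end = period_bounds
    n_pre = (boundary - start).days
    n_stay = (end - boundary).days
    rows = []
    eligible: dict[str, bool] = {}
    sensor_usable: dict[tuple[str, str], bool] = {}
    valid_map: dict[tuple[str, str], set] = {}
    for pid, streams in all_streams.items():
        any_ok = False
        for sensor in SENSORS:
            vdays = valid_days_for_sensor(streams, sensor, thresholds)
            vdays = {d for d in vdays if start <= d < end}
            valid_map[(pid, sensor)] = vdays
            pre = sum(1 for d in vdays if d < boundary)
            stay = len(vdays) - pre
            usable = pre >= thresholds.min_valid_days and stay >= thresholds.min_valid_days
            sensor_usable[(pid, sensor)] = usable
            any_ok = any_ok or usable
            rows.append({"participant_id": pid, "sensor": sensor, "period": "pre",
                         "n_valid_days": pre,
                         "expected_fraction": pre / n_pre if n_pre else 0.0,
                         "usable": usable})
            rows.append({"participant_id": pid, "sensor": sensor, "period": "stay",
                         "n_valid_days": stay,
                         "expected_fraction": stay / n_stay if n_stay else 0.0,
                         "usable": usable})
        eligible[pid] = any_ok
    return CoverageReport(
        table=pd.DataFrame(rows),
        eligible=eligible,
        sensor_usable=sensor_usable,
        valid_days=valid_map,
    )
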