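"""Behavioral feature extraction.

For every sensor, daily features are computed inside each time-of-day epoch,
averaged over the valid days of each study period (optionally restricted to
weekdays or weekends — together with the epoch this realizes the 15 temporal
slices), and differenced (stay-at-home average minus pre-period average) to
form behavior-change features. Each of the six sensors yields one
participants x (slice, feature) matrix; the 15 slices are concatenated
column-wise.

Location features follow common mobility-sensing conventions: location
variance on raw degrees, haversine travel distance, radius of gyration,
places from 30 m single-linkage clustering (clusters with at least 3 fixes),
entropy over time per place, fraction of time at home (the cluster holding
the most night-time fixes across the whole period), and a 24-hour movement
regularity index (mean Pearson correlation between consecutive days' hourly
dominant-place vectors).
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .constants import EPOCH_ORDER, SENSORS
from .ingest import ALL_SLICES

EPOCH4 = ("night", "morning", "afternoon", "evening")

#: Fixed per-sensor feature catalog; the single source of truth for column
#: naming and ordering.
FEATURE_CATALOG: dict[str, tuple[str, ...]] = {
    "calls": (
        "n_incoming", "n_outgoing", "n_missed",
        "total_duration_incoming_s", "total_duration_outgoing_s", "mean_duration_s",
    ),
    "screen": (
        "n_unlock_episodes", "total_interaction_min", "mean_episode_min", "max_episode_min",
    ),
    "location": (
        "log_location_variance", "total_distance_m", "radius_of_gyration_m",
        "n_places", "entropy_bits", "normalized_entropy",
        "time_at_home_fraction", "regularity_24h",
    ),
    "steps": (
        "total_steps", "active_min", "sedentary_bout_count", "max_active_streak_min",
    ),
    "sleep": (
        "asleep_min", "awake_min", "restless_min", "n_awakenings",
        "sleep_efficiency", "onset_min_after_midnight", "offset_min_after_midnight",
    ),
    "heart": (
        "mean_bpm", "std_bpm", "min_bpm", "max_bpm",
        "nonexercise_mean_bpm", "exercise_fraction",
    ),
}

#: Features that are zero (not missing) on a valid phone-alive day with no
#: events.
ZERO_FILL: dict[str, tuple[str, ...]] = {
    "calls": ("n_incoming", "n_outgoing", "n_missed",
              "total_duration_incoming_s", "total_duration_outgoing_s"),
    "screen": ("n_unlock_episodes", "total_interaction_min"),
}


@dataclasses.dataclass
class FeatureConfig:
    """Tunable feature-extraction parameters (defaults follow common
    mobile-sensing conventions)."""

    cluster_eps_m: float = 30.0       # linkage radius for place clustering
    cluster_min_fixes: int = 3        # minimum fixes for a cluster to be a place
    cluster_snap_m: float = 6.0       # pre-clustering grid snap (speed, << eps)
    active_steps_per_min: float = 60.0
    sedentary_steps_per_min: float = 10.0
    sedentary_bout_min: int = 30
    age_years: float = 40.0           # used for the exercise heart-rate zone
    hr_zone_factor: float = 0.5       # zone boundary = factor * (220 - age)
    regularity_min_bin_fraction: float = 0.5  # of the epoch's hourly bins

    @property
    def hr_zone_bpm(self) -> float:
        return self.hr_zone_factor * (220.0 - self.age_years)


def feature_keys(sensor: str) -> list[tuple[str, str, str]]:
    """(sensor, slice, feature) column keys in canonical order."""
    return [(sensor, sl.name, f) for sl in ALL_SLICES for f in FEATURE_CATALOG[sensor]]


# ---------------------------------------------------------------------------
# Small geometry helpers
# ---------------------------------------------------------------------------

_EARTH_R = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters between coordinate arrays (degrees)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * _EARTH_R * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _project_m(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Equirectangular projection to meters, centered on the centroid (the
    centering keeps coordinates small enough that second-moment formulas do
    not lose precision)."""
    if len(lat) == 0:
        return np.empty((0, 2))
    lat0 = np.radians(np.mean(lat))
    x = np.radians(lon - np.mean(lon)) * np.cos(lat0) * _EARTH_R
    y = np.radians(lat - np.mean(lat)) * _EARTH_R
    return np.column_stack([x, y])


def cluster_fixes(xy: np.ndarray, eps_m: float, min_fixes: int, snap_m: float = 0.0) -> np.ndarray:
    """Single-linkage place clustering.

    Two fixes are linked when within ``eps_m``; a connected component with at
    least ``min_fixes`` fixes is a place. Returns per-fix place labels
    (0..k-1) or -1 for transient fixes. ``snap_m`` optionally deduplicates
    fixes onto a grid much finer than ``eps_m`` before linking (pure speed-up
    for large inputs).
    """
    n = len(xy)
    if n == 0:
        return np.empty(0, dtype=int)
    if snap_m > 0:
        cells = np.round(xy / snap_m).astype(np.int64)
        uniq, inverse, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
        pts = uniq * snap_m
    else:
        pts = xy
        inverse = np.arange(n)
        counts = np.ones(n, dtype=int)
    m = len(pts)
    pairs = cKDTree(pts).query_pairs(eps_m, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
    )
    _, comp = connected_components(adj, directed=False)
    comp_sizes = np.bincount(comp, weights=counts)
    keep = comp_sizes >= min_fixes
    # stable place ids ordered by decreasing size then component index
    order = np.lexsort((np.arange(len(comp_sizes)), -comp_sizes))
    rank = np.full(len(comp_sizes), -1, dtype=int)
    nxt = 0
    for c in order:
        if keep[c]:
            rank[c] = nxt
            nxt += 1
    return rank[comp][inverse]


def place_entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of time shares across places."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if len(counts) <= 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Per-sensor daily tables
# ---------------------------------------------------------------------------
# Each builder returns a long DataFrame with columns
#   date (datetime64), epoch (one of the 5 names), <features...>
# holding one row per (day, epoch) with any data. Day-validity filtering is
# applied by the caller.

def _with_epoch(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    ts = out["timestamp"]
    out["date"] = ts.dt.normalize()
    out["epoch"] = pd.Categorical.from_codes(
        ts.dt.hour.to_numpy() // 6, categories=EPOCH4
    )
    return out


def _concat_epochs(per_epoch: pd.DataFrame, all_day: pd.DataFrame) -> pd.DataFrame:
    all_day = all_day.copy()
    all_day["epoch"] = "all_day"
    out = pd.concat([all_day, per_epoch], ignore_index=True)
    out["epoch"] = out["epoch"].astype(str)
    return out


def calls_daily(df: pd.DataFrame, alive_days: set | None = None) -> pd.DataFrame:
    """Daily call features per epoch; zero-filled on phone-alive days."""
    frames = []
    if len(df):
        d = _with_epoch(df)
        d["dur"] = d["duration_s"].astype(float)
        for group_cols in (["date", "epoch"], ["date"]):
            g = d.groupby(group_cols, observed=True)
            agg = g.agg(
                n_incoming=("call_type", lambda s: int((s == "incoming").sum())),
                n_outgoing=("call_type", lambda s: int((s == "outgoing").sum())),
                n_missed=("call_type", lambda s: int((s == "missed").sum())),
            )
            dur_in = d.loc[d["call_type"] == "incoming"].groupby(group_cols, observed=True)["dur"].sum()
            dur_out = d.loc[d["call_type"] == "outgoing"].groupby(group_cols, observed=True)["dur"].sum()
            agg["total_duration_incoming_s"] = dur_in.reindex(agg.index).fillna(0.0)
            agg["total_duration_outgoing_s"] = dur_out.reindex(agg.index).fillna(0.0)
            n_completed = agg["n_incoming"] + agg["n_outgoing"]
            total = agg["total_duration_incoming_s"] + agg["total_duration_outgoing_s"]
            agg["mean_duration_s"] = np.where(n_completed > 0, total / n_completed.replace(0, 1), np.nan)
            agg = agg.reset_index()
            if "epoch" not in agg.columns:
                frames.append((None, agg))
            else:
                frames.append(("epoch", agg))
        per_epoch = next(a for k, a in frames if k == "epoch")
        all_day = next(a for k, a in frames if k is None)
        out = _concat_epochs(per_epoch, all_day)
    else:
        out = pd.DataFrame(columns=["date", "epoch", *FEATURE_CATALOG["calls"]])
    return _zero_fill(out, "calls", alive_days)


def _zero_fill(table: pd.DataFrame, sensor: str, alive_days: set | None) -> pd.DataFrame:
    """Add zero rows for phone-alive (day, epoch) cells without events."""
    if alive_days is None:
        return table
    full = pd.MultiIndex.from_product(
        [pd.to_datetime(sorted(alive_days)), list(EPOCH_ORDER)], names=["date", "epoch"]
    )
    table = table.set_index(["date", "epoch"]).reindex(full)
    for col in ZERO_FILL[sensor]:
        table[col] = table[col].fillna(0.0)
    return table.reset_index()


def screen_episodes(df: pd.DataFrame) -> pd.DataFrame:
    """Pair each unlock with the next lock/off event; one row per episode.

    An episode is attributed to the calendar day and epoch of its unlock.
    """
    if df.empty:
        return pd.DataFrame(columns=["timestamp", "duration_min"])
    ts = df["timestamp"].to_numpy()
    ev = df["event"].to_numpy()
    unlock_t = ts[ev == "unlock"]
    end_t = ts[(ev == "off") | (ev == "lock")]
    if len(unlock_t) == 0 or len(end_t) == 0:
        return pd.DataFrame(columns=["timestamp", "duration_min"])
    idx = np.searchsorted(end_t, unlock_t, side="left")
    ok = idx < len(end_t)
    unlock_t = unlock_t[ok]
    dur = (end_t[idx[ok]] - unlock_t) / np.timedelta64(1, "m")
    keep = dur >= 0
    return pd.DataFrame({"timestamp": unlock_t[keep], "duration_min": dur[keep]})


def screen_daily(df: pd.DataFrame, alive_days: set | None = None) -> pd.DataFrame:
    eps = screen_episodes(df)
    if len(eps):
        d = _with_epoch(eps)
        parts = []
        for group_cols in (["date", "epoch"], ["date"]):
            g = d.groupby(group_cols, observed=True)["duration_min"]
            agg = g.agg(
                n_unlock_episodes="count",
                total_interaction_min="sum",
                mean_episode_min="mean",
                max_episode_min="max",
            ).reset_index()
            parts.append(agg)
        out = _concat_epochs(parts[0], parts[1])
    else:
        out = pd.DataFrame(columns=["date", "epoch", *FEATURE_CATALOG["screen"]])
    return _zero_fill(out, "screen", alive_days)


def heart_daily(df: pd.DataFrame, config: FeatureConfig) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=["date", "epoch", *FEATURE_CATALOG["heart"]])
    d = _with_epoch(df)
    thr = config.hr_zone_bpm
    bpm = d["bpm"].astype(float)
    d["bpm_f"] = bpm
    d["bpm_nonex"] = bpm.where(bpm < thr)
    d["is_ex"] = (bpm >= thr).astype(float)
    parts = []
    for group_cols in (["date", "epoch"], ["date"]):
        g = d.groupby(group_cols, observed=True)
        agg = g.agg(
            mean_bpm=("bpm_f", "mean"),
            std_bpm=("bpm_f", lambda s: float(np.std(s))),
            min_bpm=("bpm_f", "min"),
            max_bpm=("bpm_f", "max"),
            nonexercise_mean_bpm=("bpm_nonex", "mean"),
            exercise_fraction=("is_ex", "mean"),
        ).reset_index()
        parts.append(agg)
    return _concat_epochs(parts[0], parts[1])


def _run_table(tmin, group_id, flag):
    """Run-length encode ``flag`` with breaks at non-consecutive minutes or
    group changes; returns (run_group, run_len, run_flag)."""
    n = len(tmin)
    if n == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0, bool)
    brk = np.ones(n, dtype=bool)
    brk[1:] = (np.diff(tmin) != 1) | (group_id[1:] != group_id[:-1]) | (flag[1:] != flag[:-1])
    run_id = np.cumsum(brk) - 1
    run_len = np.bincount(run_id)
    starts = np.flatnonzero(brk)
    return group_id[starts], run_len, flag[starts]


def steps_daily(df: pd.DataFrame, config: FeatureConfig) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=["date", "epoch", *FEATURE_CATALOG["steps"]])
    d = _with_epoch(df)
    steps = d["steps"].astype(float).to_numpy()
    d["active"] = steps >= config.active_steps_per_min
    parts = []
    tmin = (d["timestamp"].astype("int64") // 60_000_000_000).to_numpy()
    date_codes = pd.factorize(d["date"])[0]
    epoch_codes = d["epoch"].cat.codes.to_numpy()
    for mode, group_cols in (("epoch", ["date", "epoch"]), ("all", ["date"])):
        g = d.groupby(group_cols, observed=True)
        agg = g.agg(
            total_steps=("steps", "sum"),
            active_min=("active", "sum"),
        )
        gid = date_codes * 8 + (epoch_codes if mode == "epoch" else 0)
        # active streaks
        rg, rl, rf = _run_table(tmin, gid, d["active"].to_numpy())
        streak = pd.Series(rl[rf], index=rg[rf]).groupby(level=0).max()
        # sedentary bouts
        sed = steps < config.sedentary_steps_per_min
        rg2, rl2, rf2 = _run_table(tmin, gid, sed)
        long_sed = rf2 & (rl2 >= config.sedentary_bout_min)
        bouts = pd.Series(rl2[long_sed], index=rg2[long_sed]).groupby(level=0).size()
        key = (
            pd.Series(date_codes * 8 + epoch_codes, index=d.index)
            if mode == "epoch"
            else pd.Series(date_codes * 8, index=d.index)
        )
        lookup = d.assign(_gid=key).groupby(group_cols, observed=True)["_gid"].first()
        agg["max_active_streak_min"] = streak.reindex(lookup.to_numpy()).fillna(0.0).to_numpy()
        agg["sedentary_bout_count"] = bouts.reindex(lookup.to_numpy()).fillna(0.0).to_numpy()
        agg = agg.reset_index()[
            ["date"] + (["epoch"] if mode == "epoch" else [])
            + ["total_steps", "active_min", "sedentary_bout_count", "max_active_streak_min"]
        ]
        parts.append(agg)
    return _concat_epochs(parts[0], parts[1])


_SLEEP_CODE = {"asleep": 0, "restless": 1, "awake": 2, "unknown": 3}


def sleep_daily(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=["date", "epoch", *FEATURE_CATALOG["sleep"]])
    d = _with_epoch(df)
    code = d["status"].map(_SLEEP_CODE).to_numpy()
    tmin = (d["timestamp"].astype("int64") // 60_000_000_000).to_numpy()
    minute_of_day = (d["timestamp"].dt.hour * 60 + d["timestamp"].dt.minute).to_numpy()
    d["asleep"] = (code == 0).astype(float)
    d["restless"] = (code == 1).astype(float)
    d["awake"] = (code == 2).astype(float)
    d["mod_asleep"] = np.where(code == 0, minute_of_day, np.nan)
    date_codes = pd.factorize(d["date"])[0]
    epoch_codes = d["epoch"].cat.codes.to_numpy()
    parts = []
    for mode, group_cols in (("epoch", ["date", "epoch"]), ("all", ["date"])):
        gid = date_codes * 8 + (epoch_codes if mode == "epoch" else 0)
        trans = np.zeros(len(d))
        if len(d) > 1:
            trans[1:] = (
                (code[:-1] == 0) & (code[1:] == 2)
                & (np.diff(tmin) == 1) & (gid[1:] == gid[:-1])
            ).astype(float)
        d["_trans"] = trans
        g = d.groupby(group_cols, observed=True)
        agg = g.agg(
            asleep_min=("asleep", "sum"),
            awake_min=("awake", "sum"),
            restless_min=("restless", "sum"),
            n_awakenings=("_trans", "sum"),
            onset_min_after_midnight=("mod_asleep", "min"),
            offset_min_after_midnight=("mod_asleep", "max"),
        ).reset_index()
        denom = agg["asleep_min"] + agg["awake_min"] + agg["restless_min"]
        agg["sleep_efficiency"] = np.where(denom > 0, agg["asleep_min"] / denom.replace(0, 1), 0.0)
        agg["offset_min_after_midnight"] = agg["offset_min_after_midnight"] + 1.0
        parts.append(agg)
    return _concat_epochs(parts[0], parts[1])


# --- location --------------------------------------------------------------

@dataclasses.dataclass
class LocationContext:
    """Whole-period place structure for one participant."""

    labels: np.ndarray          # global place label per fix (-1 transient)
    home_label: int             # place holding the most night-epoch fixes
    dominant: pd.DataFrame      # rows: date, hour, dominant place label


def build_location_context(df: pd.DataFrame, config: FeatureConfig) -> LocationContext:
    if df.empty:
        return LocationContext(np.empty(0, int), -1, pd.DataFrame(columns=["date", "hour", "place"]))
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    xy = _project_m(lat, lon)
    labels = cluster_fixes(xy, config.cluster_eps_m, config.cluster_min_fixes,
                           snap_m=config.cluster_snap_m)
    hours = df["timestamp"].dt.hour.to_numpy()
    night = labels[(hours < 6) & (labels >= 0)]
    if len(night):
        home = int(np.bincount(night).argmax())
    elif (labels >= 0).any():
        home = int(np.bincount(labels[labels >= 0]).argmax())
    else:
        home = -1
    dom = pd.DataFrame({
        "date": df["timestamp"].dt.normalize().to_numpy(),
        "hour": hours,
        "place": labels,
    })
    dom = dom[dom["place"] >= 0]
    if len(dom):
        counts = dom.groupby(["date", "hour", "place"], observed=True).size().reset_index(name="n")
        counts = counts.sort_values(["date", "hour", "n", "place"],
                                    ascending=[True, True, False, True], kind="stable")
        dominant = counts.drop_duplicates(["date", "hour"])[["date", "hour", "place"]]
    else:
        dominant = pd.DataFrame(columns=["date", "hour", "place"])
    return LocationContext(labels=labels, home_label=home, dominant=dominant)


def location_daily(
    df: pd.DataFrame, config: FeatureConfig, context: LocationContext | None = None
) -> pd.DataFrame:
    """Daily location features per epoch (regularity_24h is period-level and
    filled in separately)."""
    if df.empty:
        return pd.DataFrame(columns=["date", "epoch", *FEATURE_CATALOG["location"]])
    if context is None:
        context = build_location_context(df, config)
    d = _with_epoch(df)
    lat = d["lat"].to_numpy(float)
    lon = d["lon"].to_numpy(float)
    xy = _project_m(lat, lon)
    d["x"], d["y"] = xy[:, 0], xy[:, 1]
    d["x2"], d["y2"] = xy[:, 0] ** 2, xy[:, 1] ** 2
    d["at_home"] = (context.labels == context.home_label).astype(float) if context.home_label >= 0 else 0.0
    date_codes, date_uniq = pd.factorize(d["date"])
    epoch_codes = d["epoch"].cat.codes.to_numpy()
    # consecutive-fix distances (stream is time-sorted)
    dist = np.zeros(len(d))
    if len(d) > 1:
        dist[1:] = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    parts = []
    for mode, group_cols in (("epoch", ["date", "epoch"]), ("all", ["date"])):
        gid = date_codes * 8 + (epoch_codes if mode == "epoch" else 0)
        dd = dist.copy()
        if len(d) > 1:
            dd[1:][gid[1:] != gid[:-1]] = 0.0
        dd[0] = 0.0
        d["_dist"] = dd
        g = d.groupby(group_cols, observed=True)
        agg = g.agg(
            var_lat=("lat", lambda s: float(np.var(s))),
            var_lon=("lon", lambda s: float(np.var(s))),
            total_distance_m=("_dist", "sum"),
            mx=("x", "mean"), my=("y", "mean"),
            mx2=("x2", "mean"), my2=("y2", "mean"),
            time_at_home_fraction=("at_home", "mean"),
        )
        agg["log_location_variance"] = np.log(agg["var_lat"] + agg["var_lon"] + 1e-10)
        rog2 = (agg["mx2"] - agg["mx"] ** 2) + (agg["my2"] - agg["my"] ** 2)
        agg["radius_of_gyration_m"] = np.sqrt(np.clip(rog2, 0.0, None))
        # per-day place clustering within the slice
        n_places, ent, nent = [], [], []
        indices = g.indices
        for key in agg.index:
            idx = indices[key]
            sub = cluster_fixes(xy[idx], config.cluster_eps_m, config.cluster_min_fixes)
            k = int(sub.max()) + 1 if len(sub) and sub.max() >= 0 else 0
            counts = np.bincount(sub[sub >= 0], minlength=k) if k else np.empty(0)
            e = place_entropy_bits(counts)
            n_places.append(k)
            ent.append(e)
            nent.append(e / np.log2(k) if k > 1 else 0.0)
        agg["n_places"] = n_places
        agg["entropy_bits"] = ent
        agg["normalized_entropy"] = nent
        agg["regularity_24h"] = np.nan
        agg = agg.reset_index()[
            ["date"] + (["epoch"] if mode == "epoch" else [])
            + list(FEATURE_CATALOG["location"])
        ]
        parts.append(agg)
    return _concat_epochs(parts[0], parts[1])


def regularity_24h(
    context: LocationContext,
    dates: pd.DatetimeIndex,
    epoch: str,
    min_bin_fraction: float = 0.5,
) -> float:
    """Mean Pearson correlation between consecutive days' hourly
    dominant-place vectors, over the given days and the epoch's hour bins.

    Days observing fewer than ``min_bin_fraction`` of the epoch's bins are
    excluded; a pair contributes when the days are calendar-adjacent and share
    at least two bins with variance on both sides.
    """
    from .constants import EPOCHS

    lo, hi = EPOCHS[epoch]
    n_bins = hi - lo
    dom = context.dominant
    dom = dom[dom["date"].isin(dates) & (dom["hour"] >= lo) & (dom["hour"] < hi)]
    if dom.empty:
        return np.nan
    pivot = dom.pivot_table(index="date", columns="hour", values="place", aggfunc="first")
    enough = pivot.notna().sum(axis=1) >= np.ceil(min_bin_fraction * n_bins)
    pivot = pivot[enough]
    if len(pivot) < 2:
        return np.nan
    days = pivot.index
    vals = pivot.to_numpy(float)
    rs = []
    for i in range(len(days) - 1):
        if (days[i + 1] - days[i]).days != 1:
            continue
        a, b = vals[i], vals[i + 1]
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < 2:
            continue
        aa, bb = a[ok], b[ok]
        if np.std(aa) == 0 or np.std(bb) == 0:
            # a constant, identical routine is perfectly regular; constant
            # but different days are maximally irregular; mixed pairs are
            # uninformative and skipped
            if np.std(aa) == 0 and np.std(bb) == 0:
                rs.append(1.0 if aa[0] == bb[0] else 0.0)
            continue
        rs.append(float(np.corrcoef(aa, bb)[0, 1]))
    return float(np.mean(rs)) if rs else np.nan


# ---------------------------------------------------------------------------
# Single-day convenience API
# ---------------------------------------------------------------------------

def daily_features(
    sensor: str,
    records: pd.DataFrame,
    config: FeatureConfig | None = None,
    location_context: LocationContext | None = None,
    phone_alive: bool = True,
) -> dict[str, float]:
    """Features for one participant, one calendar day, one slice of records.

    An empty slice-day yields missing values, except count-style call/screen
    features which are 0 on phone-alive days. For location, a whole-period
    :class:`LocationContext` may be supplied; otherwise the given records
    stand in for the period (and ``regularity_24h`` is undefined for a single
    day).
    """
    config = config or FeatureConfig()
    names = FEATURE_CATALOG[sensor]
    out = {f: np.nan for f in names}
    if records.empty:
        if phone_alive and sensor in ZERO_FILL:
            out.update({f: 0.0 for f in ZERO_FILL[sensor]})
        return out
    builders = {
        "calls": lambda: calls_daily(records),
        "screen": lambda: screen_daily(records),
        "heart": lambda: heart_daily(records, config),
        "steps": lambda: steps_daily(records, config),
        "sleep": lambda: sleep_daily(records),
        "location": lambda: location_daily(records, config, location_context),
    }
    table = builders[sensor]()
    row = table[table["epoch"] == "all_day"]
    if row.empty:
        return out
    # single day in, so aggregate over whatever epoch rows exist
    vals = row.iloc[0]
    for f in names:
        if f in vals.index:
            out[f] = float(vals[f]) if pd.notna(vals[f]) else np.nan
    return out


# ---------------------------------------------------------------------------
# Period averaging and behavior change
# ---------------------------------------------------------------------------

def period_average(
    daily_rows: pd.DataFrame,
    period: tuple[datetime.date, datetime.date],
    dayset: str = "all_days",
) -> pd.Series:
    """Unweighted mean of daily feature values over the period's days in the
    dayset; missing when no valid day exists. Day order never matters."""
    lo = pd.Timestamp(period[0])
    hi = pd.Timestamp(period[1])
    d = daily_rows
    mask = (d["date"] >= lo) & (d["date"] < hi)
    if dayset == "weekdays":
        mask &= d["date"].dt.dayofweek < 5
    elif dayset == "weekends":
        mask &= d["date"].dt.dayofweek >= 5
    sub = d.loc[mask].drop(columns=[c for c in ("date", "epoch") if c in d.columns])
    if sub.empty:
        return pd.Series(np.nan, index=sub.columns)
    return sub.mean(axis=0, skipna=True)


def behavior_change(pre_avg: pd.Series, stay_avg: pd.Series) -> pd.Series:
    """Stay-at-home average minus pre-period average; missing when either
    side is missing. Raises on key mismatch."""
    if not pre_avg.index.equals(stay_avg.index):
        raise ValueError("behavior_change: feature keys differ between periods")
    return stay_avg - pre_avg


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ParticipantDaily:
    """Daily feature tables (valid days only) for one participant."""

    tables: dict[str, pd.DataFrame]
    location_context: LocationContext | None


def participant_daily(
    streams: Mapping[str, pd.DataFrame],
    valid_days: Mapping[str, set],
    config: FeatureConfig | None = None,
) -> ParticipantDaily:
    """Compute all six sensors' daily tables, restricted to valid days."""
    config = config or FeatureConfig()
    tables: dict[str, pd.DataFrame] = {}
    loc_ctx: LocationContext | None = None

    def restrict(table: pd.DataFrame, sensor: str) -> pd.DataFrame:
        days = valid_days.get(sensor, set())
        if table.empty:
            return table
        keep = table["date"].isin({pd.Timestamp(d) for d in days})
        return table.loc[keep].reset_index(drop=True)

    alive = valid_days.get("calls", set())
    tables["calls"] = restrict(calls_daily(streams["calls"], alive_days=alive), "calls")
    tables["screen"] = restrict(screen_daily(streams["screen"], alive_days=alive), "screen")
    tables["heart"] = restrict(heart_daily(streams["heart"], config), "heart")
    tables["steps"] = restrict(steps_daily(streams["steps"], config), "steps")
    tables["sleep"] = restrict(sleep_daily(streams["sleep"]), "sleep")
    loc = streams["location"]
    # context from valid-day fixes only, so home/places reflect usable data
    vdays = {pd.Timestamp(d) for d in valid_days.get("location", set())}
    loc = loc.loc[loc["timestamp"].dt.normalize().isin(vdays)].reset_index(drop=True)
    loc_ctx = build_location_context(loc, config)
    tables["location"] = location_daily(loc, config, loc_ctx)
    return ParticipantDaily(tables=tables, location_context=loc_ctx)


def participant_deltas(
    pdaily: ParticipantDaily,
    period_bounds: tuple[datetime.date, datetime.date, datetime.date],
    sensor_usable: Mapping[str, bool],
    config: FeatureConfig | None = None,
) -> dict[str, pd.Series]:
    """Behavior-change vectors (one per sensor) for one participant.

    Sensors without enough valid days in either period yield all-missing
    vectors; the participant keeps their row, and missing cells are imputed
    fold-aware during modeling.
    """
    config = config or FeatureConfig()
    start, boundary, end = period_bounds
    pre = (start, boundary)
    stay = (boundary, end)
    out: dict[str, pd.Series] = {}
    for sensor in SENSORS:
        keys = pd.MultiIndex.from_tuples(feature_keys(sensor))
        if not sensor_usable.get(sensor, False):
            out[sensor] = pd.Series(np.nan, index=keys)
            continue
        table = pdaily.tables[sensor]
        vals = {}
        for sl in ALL_SLICES:
            sub = table[table["epoch"] == sl.epoch] if len(table) else table
            cols = [c for c in FEATURE_CATALOG[sensor] if c != "regularity_24h"]
            if len(sub):
                pre_avg = period_average(sub[["date", *cols]], pre, sl.dayset)
                stay_avg = period_average(sub[["date", *cols]], stay, sl.dayset)
                delta = behavior_change(pre_avg, stay_avg)
            else:
                delta = pd.Series(np.nan, index=cols)
            for f in cols:
                vals[(sensor, sl.name, f)] = delta.get(f, np.nan)
            if sensor == "location":
                ctx = pdaily.location_context
                dates_pre = pd.to_datetime(
                    sorted(d for d in sub["date"].unique() if d < pd.Timestamp(boundary))
                ) if len(sub) else pd.DatetimeIndex([])
                dates_stay = pd.to_datetime(
                    sorted(d for d in sub["date"].unique() if d >= pd.Timestamp(boundary))
                ) if len(sub) else pd.DatetimeIndex([])

                def _dayset_dates(dates):
                    if sl.dayset == "weekdays":
                        return dates[dates.dayofweek < 5]
                    if sl.dayset == "weekends":
                        return dates[dates.dayofweek >= 5]
                    return dates

                r_pre = regularity_24h(ctx, _dayset_dates(dates_pre), sl.epoch,
                                       config.regularity_min_bin_fraction)
                r_stay = regularity_24h(ctx, _dayset_dates(dates_stay), sl.epoch,
                                        config.regularity_min_bin_fraction)
                vals[(sensor, sl.name, "regularity_24h")] = (
                    r_stay - r_pre if pd.notna(r_pre) and pd.notna(r_stay) else np.nan
                )
        out[sensor] = pd.Series(vals).reindex(keys)
    return out


def build_matrices(
    per_participant: Mapping[str, dict[str, pd.Series]],
    eligible: Mapping[str, bool],
) -> dict[str, pd.DataFrame]:
    """Assemble per-sensor behavior-change matrices over eligible
    participants (rows ordered by participant id)."""
    pids = sorted(p for p in per_participant if eligible.get(p, False))
    if not pids:
        raise ValueError("no eligible participants: cannot build feature matrices")
    out: dict[str, pd.DataFrame] = {}
    for sensor in SENSORS:
        rows = [per_participant[p][sensor] for p in pids]
        mat = pd.DataFrame(rows, index=pids)
        mat.columns = pd.MultiIndex.from_tuples(feature_keys(sensor),
                                                names=["sensor", "slice", "feature"])
        out[sensor] = mat
    return out
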