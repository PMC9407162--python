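"""Synthetic cohort generator.

Emulates the study's data collection: for each virtual participant, raw
smartphone streams (calls, screen, location) and fitness-tracker streams
(heart rate, sleep, steps) over a study window split into a pre–stay-at-home
period and a stay-at-home period, plus questionnaire administrations (PHQ-9
biweekly; MSRS-R, MFIS-5, PSQI every 4 weeks).

Each participant carries a latent severity per outcome drawn from a shared
factor model (so outcomes are positively inter-correlated), and binary ground
truth labels from thresholding those severities. Outcome-linked behavior
changes are injected at the generative-parameter level — call rates, resting
heart rate, propensity to leave home, step budgets, sleep parameters — and
only for records dated in the stay-at-home period, so the downstream
behavior-change feature extraction is genuinely exercised.

Sampling rates follow the study: location at 1 sample per 10 minutes; steps,
sleep and heart rate at 1 sample per minute; calls and screen as event
streams.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .constants import (
    DEFAULT_PERIOD_BOUNDARY,
    DEFAULT_STUDY_END,
    DEFAULT_STUDY_START,
    INSTRUMENTS,
    OUTCOMES,
    SENSORS,
    STREAM_COLUMNS,
)


class ConfigurationError(ValueError):
    """Invalid cohort configuration (dates or probabilities)."""


#: Strong outcome-linked parameter shifts, in units of the between-participant
#: standard deviation of each generative parameter. These defaults plant
#: recoverable signal in the calls, heart, location, screen, sleep and steps
#: sensors; pass ``effect_size={}`` for a null (no-effect) cohort.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "depression": {"call_rate": 1.5, "resting_hr": -1.5, "leave_home": -1.5},
    "msrsr": {"step_budget": -1.5, "leave_home": -1.0, "restlessness": 1.0},
    "mfis5": {"step_budget": -1.0, "sleep_duration": 1.5, "screen_rate": -1.0},
    "psqi": {"restlessness": 1.5, "bed_time": 1.0, "screen_rate": 1.0},
}

#: One between-participant SD of each shiftable generative parameter.
_PARAM_SD = {
    "call_rate": 0.4,      # on log(calls/day)
    "resting_hr": 5.0,     # bpm
    "leave_home": 0.8,     # logit units
    "step_budget": 2000.0, # steps/day
    "screen_rate": 10.0,   # unlock episodes/day
    "sleep_duration": 40.0,  # minutes
    "bed_time": 45.0,      # minutes
    "restlessness": 0.04,  # fraction of sleep minutes
}

#: Loadings of each outcome's latent severity on the shared factor.
_FACTOR_LOADING = {"depression": 0.7, "msrsr": 0.6, "mfis5": 0.7, "psqi": 0.5}


@dataclasses.dataclass
class MissingnessConfig:
    """Per-sensor daily dropout and within-day gap model.

    ``daily_dropout`` is the probability that a whole sensor-day is lost;
    ``gap_rate`` the per-day probability of losing one contiguous 1-4 h window
    of a sampled stream; ``insufficient_fraction`` the fraction of
    participants whose pre-period data are almost entirely removed, to
    exercise the eligibility exclusion rule.
    """

    daily_dropout: float | Mapping[str, float] = 0.03
    gap_rate: float = 0.05
    insufficient_fraction: float = 6 / 56

    def dropout_for(self, sensor: str) -> float:
        if isinstance(self.daily_dropout, Mapping):
            return float(self.daily_dropout.get(sensor, 0.0))
        return float(self.daily_dropout)

    def validate(self) -> None:
        probs = [self.gap_rate, self.insufficient_fraction]
        if isinstance(self.daily_dropout, Mapping):
            probs += list(self.daily_dropout.values())
        else:
            probs.append(self.daily_dropout)
        for p in probs:
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_participants: int = 56
    seed: int = 0
    study_start: datetime.date = DEFAULT_STUDY_START
    period_boundary: datetime.date = DEFAULT_PERIOD_BOUNDARY
    study_end: datetime.date = DEFAULT_STUDY_END
    #: per-outcome positive-label prevalence
    prevalence: dict[str, float] = dataclasses.field(
        default_factory=lambda: {o: 0.5 for o in OUTCOMES}
    )
    #: outcome -> {parameter: standardized shift} applied to positive-label
    #: participants' stay-at-home behavior
    effect_size: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {o: dict(v) for o, v in DEFAULT_EFFECTS.items()}
    )
    missingness: MissingnessConfig = dataclasses.field(default_factory=MissingnessConfig)

    def __post_init__(self) -> None:
        if not (self.study_start < self.period_boundary < self.study_end):
            raise ConfigurationError(
                "require study_start < period_boundary < study_end, got "
                f"{self.study_start} / {self.period_boundary} / {self.study_end}"
            )
        for o, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence[{o}]={p} outside [0, 1]")
        for o, shifts in self.effect_size.items():
            unknown = set(shifts) - set(_PARAM_SD)
            if unknown:
                raise ConfigurationError(f"unknown effect parameters {unknown} for {o}")
        self.missingness.validate()

    @property
    def n_pre_days(self) -> int:
        return (self.period_boundary - self.study_start).days

    @property
    def n_stay_days(self) -> int:
        return (self.study_end - self.period_boundary).days


@dataclasses.dataclass
class LatentProfile:
    """Ground-truth generative state for one participant."""

    participant_id: str
    labels: dict[str, int]
    severity: dict[str, float]
    home: tuple[float, float]
    work: tuple[float, float]
    errand: tuple[float, float]
    bed_time_min: float      # minutes after midnight (can exceed 1440)
    sleep_duration_min: float
    restlessness: float
    resting_hr: float
    step_budget: float
    call_rate: float         # calls/day
    screen_rate: float       # unlock episodes/day
    leave_home_logit: float
    age: int
    #: net stay-at-home parameter shift for this participant (label-linked)
    stay_shift: dict[str, float]
    insufficient_pre: bool = False


@dataclasses.dataclass
class Cohort:
    """In-memory cohort bundle."""

    config: CohortConfig
    profiles: list[LatentProfile]
    streams: dict[str, dict[str, pd.DataFrame]]
    questionnaires: pd.DataFrame  # participant_id, date, instrument, item_index, value
    labels: pd.DataFrame          # participant_id, outcome, severity, label

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {"participant_id": pid, "sensor": s, "n_records": len(df)}
            for pid, sdict in self.streams.items()
            for s, df in sdict.items()
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        write_cohort(self, out_dir)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _participant_rng(config: CohortConfig, index: int, stage: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index, stage]))


def make_profiles(config: CohortConfig) -> list[LatentProfile]:
    """Draw latent profiles for the whole cohort (deterministic in the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_001]))
    n = config.n_participants
    shared = rng.normal(size=n)
    severity: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for o in OUTCOMES:
        lam = _FACTOR_LOADING[o]
        sev = lam * shared + np.sqrt(1 - lam**2) * rng.normal(size=n)
        cut = ndtri(1.0 - config.prevalence.get(o, 0.0)) if config.prevalence.get(o, 0.0) < 1.0 else -np.inf
        severity[o] = sev
        labels[o] = (sev >= cut).astype(int)

    n_bad = int(round(config.missingness.insufficient_fraction * n))
    bad = set(rng.choice(n, size=n_bad, replace=False).tolist()) if n_bad else set()

    profiles = []
    for i in range(n):
        prng = _participant_rng(config, i, stage=1)
        home = (40.44 + prng.normal(0, 0.02), -79.99 + prng.normal(0, 0.03))
        work = (home[0] + prng.normal(0, 0.03), home[1] + prng.normal(0, 0.04))
        errand = (home[0] + prng.normal(0, 0.01), home[1] + prng.normal(0, 0.015))
        shift: dict[str, float] = {}
        for o in OUTCOMES:
            if labels[o][i]:
                for param, s in config.effect_size.get(o, {}).items():
                    shift[param] = shift.get(param, 0.0) + s * _PARAM_SD[param]
        profiles.append(
            LatentProfile(
                participant_id=f"p{i:03d}",
                labels={o: int(labels[o][i]) for o in OUTCOMES},
                severity={o: float(severity[o][i]) for o in OUTCOMES},
                home=home,
                work=work,
                errand=errand,
                bed_time_min=float(np.clip(prng.normal(23 * 60, 45), 20 * 60, 26 * 60)),
                sleep_duration_min=float(np.clip(prng.normal(465, 40), 300, 640)),
                restlessness=float(np.clip(prng.normal(0.08, 0.04), 0.01, 0.4)),
                resting_hr=float(prng.normal(65, 5)),
                step_budget=float(np.clip(prng.normal(8000, 2000), 1500, None)),
                call_rate=float(np.exp(prng.normal(np.log(6), 0.4))),
                screen_rate=float(np.clip(prng.normal(40, 10), 5, None)),
                leave_home_logit=float(prng.normal(1.0, 0.8)),
                age=int(np.clip(round(prng.normal(45, 12)), 18, 80)),
                stay_shift=shift,
                insufficient_pre=i in bad,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Streams for one participant
# ---------------------------------------------------------------------------

def _bump_duplicate_seconds(sec: np.ndarray) -> np.ndarray:
    """Nudge duplicate timestamps forward by one second (keeps streams
    strictly increasing so ingest's deduplication never drops records)."""
    sec = sec.copy()
    while True:
        dup = np.flatnonzero(np.diff(sec) <= 0)
        if len(dup) == 0:
            return sec
        sec[dup + 1] = sec[dup] + 1


def _day_params(profile: LatentProfile, config: CohortConfig) -> dict[str, np.ndarray]:
    """Per-day generative parameters with mandate and label-linked stay shifts."""
    n_days = (config.study_end - config.study_start).days
    stay = np.array(
        [
            (config.study_start + datetime.timedelta(days=int(d))) >= config.period_boundary
            for d in range(n_days)
        ]
    )
    sh = profile.stay_shift

    def shifted(base: float, key: str, mandate: float = 0.0) -> np.ndarray:
        return np.where(stay, base + sh.get(key, 0.0) + mandate, base)

    params = {
        "stay": stay,
        "bed_time": shifted(profile.bed_time_min, "bed_time"),
        "sleep_duration": shifted(profile.sleep_duration_min, "sleep_duration"),
        "restlessness": np.clip(shifted(profile.restlessness, "restlessness"), 0.0, 0.5),
        "resting_hr": shifted(profile.resting_hr, "resting_hr"),
        # the mandate itself reduces activity and mobility for everyone
        "step_budget": np.clip(
            shifted(profile.step_budget, "step_budget", mandate=-0.15 * profile.step_budget),
            200.0, None,
        ),
        "leave_logit": shifted(profile.leave_home_logit, "leave_home", mandate=-1.5),
        "screen_rate": np.clip(shifted(profile.screen_rate, "screen_rate", mandate=5.0), 1.0, None),
    }
    # the call-rate shift acts multiplicatively (its SD is on the log rate)
    log_shift = sh.get("call_rate", 0.0)
    params["call_rate"] = np.where(
        stay, np.clip(profile.call_rate * np.exp(log_shift), 0.1, None), profile.call_rate
    )
    return params


def generate_participant_streams(
    profile: LatentProfile, config: CohortConfig, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Simulate all six raw streams for one participant.

    Each sensor draws from its own spawned generator, and stay-period
    parameter shifts never change the number of pre-period draws, so
    pre-period records are bit-identical whether or not stay-at-home shifts
    are configured.
    """
    start = config.study_start
    n_days = (config.study_end - start).days
    t0 = np.datetime64(pd.Timestamp(start), "m")
    total_min = n_days * 1440
    params = _day_params(profile, config)
    r_sleep, r_steps, r_heart, r_loc, r_calls, r_screen = rng.spawn(6)

    # --- sleep: one main episode per night plus brief interruptions ---------
    asleep_mask = np.zeros(total_min + 2880, dtype=bool)  # pad for overhang
    sleep_minutes: list[np.ndarray] = []
    sleep_status: list[np.ndarray] = []
    for d in range(n_days):
        bed = params["bed_time"][d] + r_sleep.normal(0, 25)
        dur = max(180.0, params["sleep_duration"][d] + r_sleep.normal(0, 30))
        s0 = int(d * 1440 + bed)
        s1 = int(s0 + dur)
        mins = np.arange(s0, s1)
        status = np.zeros(len(mins), dtype=np.int8)  # 0 asleep, 1 restless, 2 awake
        n_int = r_sleep.poisson(1.0 + params["restlessness"][d] * 30)
        for _ in range(n_int):
            if len(mins) < 30:
                break
            off = r_sleep.integers(5, len(mins) - 10)
            length = int(3 + r_sleep.geometric(0.25))
            kind = 1 if r_sleep.random() < 0.7 else 2
            status[off : off + length] = kind
        status[r_sleep.random(len(mins)) < 0.01] = 3  # occasional unknowns
        keep = mins < total_min
        mins, status = mins[keep], status[keep]
        asleep_mask[mins] = True
        sleep_minutes.append(mins)
        sleep_status.append(status)
    sleep_min = np.concatenate(sleep_minutes) if sleep_minutes else np.empty(0, int)
    sleep_stat = np.concatenate(sleep_status) if sleep_status else np.empty(0, np.int8)
    order = np.argsort(sleep_min, kind="stable")
    sleep_min, sleep_stat = sleep_min[order], sleep_stat[order]
    status_names = np.array(["asleep", "restless", "awake", "unknown"])
    sleep_values = status_names[sleep_stat]
    sleep_df = pd.DataFrame(
        {"timestamp": t0 + sleep_min.astype("timedelta64[m]"), "status": sleep_values}
    )
    asleep_mask = asleep_mask[:total_min]
    awake_mask = ~asleep_mask

    # --- steps --------------------------------------------------------------
    day_idx = np.arange(total_min) // 1440
    waking_per_day = np.maximum(np.bincount(day_idx, weights=awake_mask, minlength=n_days), 1.0)
    p_active = np.clip(
        (params["step_budget"] - 2.0 * waking_per_day) / (83.0 * waking_per_day), 0.005, 0.6
    )
    active = (r_steps.random(total_min) < p_active[day_idx]) & awake_mask
    steps = np.where(active, r_steps.poisson(85.0, total_min), r_steps.poisson(2.0, total_min))
    steps[asleep_mask] = 0
    workout_boost = np.zeros(total_min)
    for d in range(n_days):
        if r_steps.random() < 0.25:
            s0 = d * 1440 + int(r_steps.integers(14 * 60, 19 * 60))
            s1 = min(s0 + 30, total_min)
            steps[s0:s1] = r_steps.poisson(110.0, s1 - s0)
            workout_boost[s0:s1] = 30.0
    steps_df = pd.DataFrame(
        {"timestamp": t0 + np.arange(total_min).astype("timedelta64[m]"), "steps": steps}
    )

    # --- heart rate ---------------------------------------------------------
    hour = (np.arange(total_min) % 1440) / 60.0
    daytime = ((hour >= 8) & (hour < 22)).astype(float)
    hr = (
        params["resting_hr"][day_idx]
        + 0.07 * steps
        + 5.0 * daytime
        + workout_boost
        + r_heart.normal(0, 3, total_min)
    )
    hr = np.clip(np.round(hr), 30, 220).astype(int)
    heart_df = pd.DataFrame(
        {"timestamp": t0 + np.arange(total_min).astype("timedelta64[m]"), "bpm": hr}
    )

    # --- location (1 fix / 10 min) -----------------------------------------
    n_slots = n_days * 144
    slot_min = np.arange(n_slots) * 10
    slot_day = slot_min // 1440
    slot_hour = (slot_min % 1440) / 60.0
    place = np.zeros(n_slots, dtype=int)  # 0 home, 1 work, 2 errand
    p_out = expit(params["leave_logit"])
    dates = pd.date_range(start, periods=n_days, freq="D")
    is_weekday = np.asarray(dates.dayofweek < 5)
    # fixed-count draws first, so stay-period shifts cannot desynchronize
    # the pre-period noise stream
    noise_lat = r_loc.normal(0, 8e-5, n_slots)
    noise_lon = r_loc.normal(0, 8e-5, n_slots)
    out_day = (r_loc.random(n_days) < p_out) & is_weekday
    errand_day = r_loc.random(n_days) < 0.6 * p_out
    errand_starts = r_loc.integers(60, 115, size=n_days)  # between 10:00 and ~19:00
    errand_lens = r_loc.integers(3, 10, size=n_days)
    work_slots = (slot_hour >= 9) & (slot_hour < 17) & out_day[slot_day]
    place[work_slots] = 1
    for d in np.nonzero(errand_day)[0]:
        e0 = d * 144 + int(errand_starts[d])
        e1 = e0 + int(errand_lens[d])
        seg = slice(e0, min(e1, n_slots))
        place[seg] = np.where(place[seg] == 0, 2, place[seg])
    place[asleep_mask[np.minimum(slot_min, total_min - 1)]] = 0
    coords = np.array([profile.home, profile.work, profile.errand])
    lat = coords[place, 0] + noise_lat
    lon = coords[place, 1] + noise_lon
    location_df = pd.DataFrame(
        {
            "timestamp": t0 + slot_min.astype("timedelta64[m]"),
            "lat": np.round(lat, 6),
            "lon": np.round(lon, 6),
        }
    )

    # --- calls --------------------------------------------------------------
    n_calls = r_calls.poisson(params["call_rate"])
    hours_w = np.ones(24)
    hours_w[8:22] = 5.0
    hours_w /= hours_w.sum()
    rows_t, rows_type, rows_dur = [], [], []
    for d in range(n_days):
        k = int(n_calls[d])
        if k == 0:
            continue
        h = r_calls.choice(24, size=k, p=hours_w)
        second = (d * 1440 + h * 60) * 60 + r_calls.integers(0, 3600, size=k)
        kinds = r_calls.choice(3, size=k, p=[0.40, 0.45, 0.15])
        dur = np.where(kinds == 2, 0.0, np.round(r_calls.exponential(180.0, size=k)) + 5.0)
        rows_t.append(second)
        rows_type.append(kinds)
        rows_dur.append(dur)
    if rows_t:
        cm = np.concatenate(rows_t)
        ck = np.concatenate(rows_type)
        cd = np.concatenate(rows_dur)
        order = np.argsort(cm, kind="stable")
        cm, ck, cd = cm[order], ck[order], cd[order]
        cm = _bump_duplicate_seconds(cm)
        type_names = np.array(["incoming", "outgoing", "missed"])
        calls_df = pd.DataFrame(
            {
                "timestamp": np.datetime64(t0, "s") + cm.astype("timedelta64[s]"),
                "call_type": type_names[ck],
                "duration_s": cd,
            }
        )
    else:
        calls_df = pd.DataFrame(columns=STREAM_COLUMNS["calls"])

    # --- screen (unlock -> off episodes) ------------------------------------
    n_ep = r_screen.poisson(params["screen_rate"])
    starts_all, durs_all = [], []
    awake_idx_by_day = [
        np.nonzero(awake_mask[d * 1440 : (d + 1) * 1440])[0] for d in range(n_days)
    ]
    for d in range(n_days):
        k = int(n_ep[d])
        idx = awake_idx_by_day[d]
        if k == 0 or len(idx) == 0:
            continue
        s = np.sort(r_screen.choice(idx, size=min(k, len(idx)), replace=False)) + d * 1440
        dur = np.clip(np.exp(r_screen.normal(np.log(2.5), 0.8, size=len(s))), 0.2, 60.0)
        # drop episodes that would overlap the next unlock
        keep = np.ones(len(s), dtype=bool)
        end = -1.0
        for j in range(len(s)):
            if s[j] <= end:
                keep[j] = False
            else:
                end = s[j] + dur[j]
        starts_all.append(s[keep])
        durs_all.append(dur[keep])
    if starts_all:
        s = np.concatenate(starts_all).astype(float)
        dur = np.concatenate(durs_all)
        sec = np.concatenate([s * 60.0, (s + dur) * 60.0]).round().astype(np.int64)
        ev = np.array(["unlock"] * len(s) + ["off"] * len(s))
        order = np.argsort(sec, kind="stable")
        sec, ev = _bump_duplicate_seconds(sec[order]), ev[order]
        screen_df = pd.DataFrame(
            {"timestamp": np.datetime64(t0, "s") + sec.astype("timedelta64[s]"), "event": ev}
        )
    else:
        screen_df = pd.DataFrame(columns=STREAM_COLUMNS["screen"])

    for df in (calls_df, screen_df):
        if df.empty and not np.issubdtype(df["timestamp"].dtype, np.datetime64):
            df["timestamp"] = pd.to_datetime(df["timestamp"])
    return {
        "calls": calls_df,
        "heart": heart_df,
        "location": location_df,
        "screen": screen_df,
        "sleep": sleep_df,
        "steps": steps_df,
    }


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def inject_missingness(
    streams: dict[str, pd.DataFrame],
    config: CohortConfig,
    rng: np.random.Generator,
    insufficient_pre: bool = False,
) -> dict[str, pd.DataFrame]:
    """Remove records according to the dropout model.

    Whole sensor-days are dropped with the per-sensor daily dropout
    probability; sampled streams additionally lose a contiguous 1-4 h window
    on gap days. When ``insufficient_pre`` is set, all pre-period records
    except the first study day are removed (the participant will fail the
    eligibility rule downstream).
    """
    miss = config.missingness
    out: dict[str, pd.DataFrame] = {}
    boundary = pd.Timestamp(config.period_boundary)
    first_day_end = pd.Timestamp(config.study_start) + pd.Timedelta(days=1)
    # one child generator per sensor, in canonical order, so one stream's
    # content never shifts another stream's dropout draws
    child = dict(zip(SENSORS, rng.spawn(len(SENSORS))))
    for sensor, df in streams.items():
        rng = child.get(sensor, np.random.default_rng(0))
        if df.empty:
            out[sensor] = df
            continue
        ts = df["timestamp"]
        keep = np.ones(len(df), dtype=bool)
        p_drop = miss.dropout_for(sensor)
        days = ts.dt.normalize()
        uniq = days.unique()
        if p_drop > 0:
            dropped = set(uniq[rng.random(len(uniq)) < p_drop])
            if dropped:
                keep &= ~days.isin(dropped).to_numpy()
        if miss.gap_rate > 0 and sensor in ("heart", "steps", "sleep", "location"):
            gap_days = uniq[rng.random(len(uniq)) < miss.gap_rate]
            for d in gap_days:
                g0 = d + pd.Timedelta(minutes=int(rng.integers(0, 20 * 60)))
                g1 = g0 + pd.Timedelta(minutes=int(rng.integers(60, 240)))
                keep &= ~((ts >= g0) & (ts < g1)).to_numpy()
        if insufficient_pre:
            keep &= ((ts >= boundary) | (ts < first_day_end)).to_numpy()
        out[sensor] = df.loc[keep].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

def _spread_items(total: int, n_items: int, item_max: int) -> list[int]:
    """Distribute a total score across items as evenly as possible."""
    total = int(np.clip(total, 0, n_items * item_max))
    q, r = divmod(total, n_items)
    return [min(q + 1, item_max)] * r + [q] * (n_items - r)


def generate_questionnaires(profiles: list[LatentProfile], config: CohortConfig) -> pd.DataFrame:
    """Item-level questionnaire table at the study cadence.

    Scores track latent severity: 3 points per severity SD around the
    instrument's dichotomization threshold, plus per-administration noise, so
    period-averaged scores cross the threshold consistently with the labels.
    """
    rows: list[tuple] = []
    for i, prof in enumerate(profiles):
        rng = _participant_rng(config, i, stage=2)
        for outcome in OUTCOMES:
            meta = INSTRUMENTS[outcome]
            prev = config.prevalence.get(outcome, 0.5)
            cut = ndtri(1.0 - prev) if 0.0 < prev < 1.0 else 0.0
            target = meta["threshold"] + 3.0 * (prof.severity[outcome] - cut)
            # labels are defined by "severity >= cut"; keep averages clear of
            # the inclusive threshold on the correct side
            target += 1.0 if prof.labels[outcome] else -1.0
            date = config.study_start
            while date < config.study_end:
                score = int(round(target + rng.normal(0, 1.5)))
                lo, hi = meta["score_range"]
                score = int(np.clip(score, lo, hi))
                if prof.labels[outcome] and date >= config.period_boundary:
                    score = max(score, int(np.ceil(meta["threshold"])))
                items = _spread_items(score, meta["n_items"], meta["item_range"][1])
                for j, v in enumerate(items):
                    rows.append((prof.participant_id, date.isoformat(), meta["instrument"], j, v))
                date = date + datetime.timedelta(days=meta["cadence_days"])
    return pd.DataFrame(rows, columns=["participant_id", "date", "instrument", "item_index", "value"])


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def iter_participants(
    config: CohortConfig, profiles: list[LatentProfile] | None = None
) -> Iterator[tuple[LatentProfile, dict[str, pd.DataFrame]]]:
    """Yield (profile, streams-with-missingness) one participant at a time.

    Memory-friendly driver for large cohorts: raw minute-level streams for a
    participant can be discarded as soon as features are computed.
    """
    profiles = profiles if profiles is not None else make_profiles(config)
    for i, prof in enumerate(profiles):
        rng = _participant_rng(config, i, stage=3)
        streams = generate_participant_streams(prof, config, rng)
        streams = inject_missingness(
            streams, config, _participant_rng(config, i, stage=4), prof.insufficient_pre
        )
        yield prof, streams


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full in-memory cohort bundle (identical seed and config
    give byte-identical serialized output)."""
    profiles = make_profiles(config)
    streams = {
        prof.participant_id: s for prof, s in iter_participants(config, profiles)
    }
    questionnaires = generate_questionnaires(profiles, config)
    labels = pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "outcome": o,
                "severity": p.severity[o],
                "label": p.labels[o],
            }
            for p in profiles
            for o in OUTCOMES
        ]
    )
    return Cohort(config=config, profiles=profiles, streams=streams,
                  questionnaires=questionnaires, labels=labels)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write ``<cohort>/<participant_id>/<sensor>.csv`` plus the questionnaire
    and ground-truth label tables, with deterministic formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, sdict in cohort.streams.items():
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        for sensor, df in sdict.items():
            fmt = df.copy()
            if len(fmt):
                fmt["timestamp"] = fmt["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
            fmt.to_csv(pdir / f"{sensor}.csv", index=False, float_format="%.6f")
    cohort.questionnaires.to_csv(out / "questionnaires.csv", index=False)
    cohort.labels.to_csv(out / "labels.csv", index=False, float_format="%.6f")
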