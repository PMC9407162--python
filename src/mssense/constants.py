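"""Shared vocabulary: sensors, outcomes, instruments, epochs.

Canonical orderings defined here are the single source of truth for column
ordering everywhere else in the package.
"""

from __future__ import annotations

import datetime

#: Canonical sensor order (alphabetical): calls, heart, location, screen, sleep, steps.
SENSORS: tuple[str, ...] = ("calls", "heart", "location", "screen", "sleep", "steps")

#: Sensors sampled on a fixed grid (the rest are event streams).
SAMPLED_SENSORS: tuple[str, ...] = ("heart", "location", "sleep", "steps")
EVENT_SENSORS: tuple[str, ...] = ("calls", "screen")

#: Outcome keys in canonical order.
OUTCOMES: tuple[str, ...] = ("depression", "msrsr", "mfis5", "psqi")

#: Instrument metadata: items per administration, per-item range, total range,
#: administration cadence in days, and the dichotomization threshold applied to
#: the stay-at-home-period average (inclusive: average >= threshold -> label 1).
INSTRUMENTS: dict[str, dict] = {
    "depression": {  # PHQ-9
        "instrument": "phq9",
        "n_items": 9,
        "item_range": (0, 3),
        "score_range": (0, 27),
        "cadence_days": 14,
        "threshold": 5.0,
    },
    "msrsr": {  # MSRS-R, 8 neurological domains
        "instrument": "msrsr",
        "n_items": 8,
        "item_range": (0, 4),
        "score_range": (0, 32),
        "cadence_days": 28,
        "threshold": 6.4,
    },
    "mfis5": {  # Modified Fatigue Impact Scale, 5 items
        "instrument": "mfis5",
        "n_items": 5,
        "item_range": (0, 4),
        "score_range": (0, 20),
        "cadence_days": 28,
        "threshold": 8.0,
    },
    "psqi": {  # PSQI handled at the 7-component level
        "instrument": "psqi",
        "n_items": 7,
        "item_range": (0, 3),
        "score_range": (0, 21),
        "cadence_days": 28,
        "threshold": 9.0,
    },
}

INSTRUMENT_TO_OUTCOME = {v["instrument"]: k for k, v in INSTRUMENTS.items()}

#: Time-of-day epochs, half-open [start_hour, end_hour) windows.
EPOCHS: dict[str, tuple[int, int]] = {
    "all_day": (0, 24),
    "night": (0, 6),
    "morning": (6, 12),
    "afternoon": (12, 18),
    "evening": (18, 24),
}

#: Day-of-week sets (ISO weekday numbering, Monday=0 under pandas dayofweek).
DAYSETS: tuple[str, ...] = ("all_days", "weekdays", "weekends")

#: Epoch order used for slice enumeration (epoch-major, then dayset).
EPOCH_ORDER: tuple[str, ...] = ("all_day", "night", "morning", "afternoon", "evening")

#: Default study calendar.
DEFAULT_STUDY_START = datetime.date(2019, 11, 16)
DEFAULT_PERIOD_BOUNDARY = datetime.date(2020, 3, 23)
DEFAULT_STUDY_END = datetime.date(2020, 5, 15)

#: Expected samples per day for sampled streams (used by coverage checks).
#: Sleep is only recorded during sleep episodes, so its expectation is a
#: typical minimum main-sleep length rather than a full day of minutes.
EXPECTED_SAMPLES_PER_DAY: dict[str, int] = {
    "heart": 1440,
    "steps": 1440,
    "sleep": 360,
    "location": 144,
}

#: Stream file schemas (delimited text, one header line, ISO-8601 local times).
STREAM_COLUMNS: dict[str, list[str]] = {
    "calls": ["timestamp", "call_type", "duration_s"],
    "screen": ["timestamp", "event"],
    "location": ["timestamp", "lat", "lon"],
    "steps": ["timestamp", "steps"],
    "sleep": ["timestamp", "status"],
    "heart": ["timestamp", "bpm"],
}

CALL_TYPES = ("incoming", "outgoing", "missed")
SCREEN_EVENTS = ("on", "off", "lock", "unlock")
SLEEP_STATUSES = ("asleep", "awake", "restless", "unknown")
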