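"""Patient-reported outcomes: scoring, period averaging, dichotomization,
and outcome inter-correlations.

Instruments: PHQ-9 (depression, 9 items 0-3, total 0-27, threshold >= 5),
MSRS-R (global MS symptom burden, 8 domains 0-4, total 0-32, threshold
>= 6.4), MFIS-5 (fatigue, 5 items 0-4, total 0-20, threshold >= 8), and the
PSQI handled at its 7 component scores (each 0-3, composite 0-21, threshold
>= 9). An administration is averaged into the stay-at-home period when its
date falls on or after the period boundary; thresholds are inclusive.
"""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd
from scipy import stats

from .constants import INSTRUMENT_TO_OUTCOME, INSTRUMENTS, OUTCOMES


class ScoreValidationError(ValueError):
    """An item response falls outside the instrument's allowed range."""


def score(outcome_or_instrument: str, items) -> float:
    """Total score for one administration: the sum of item (or, for the
    PSQI, component) responses."""
    key = INSTRUMENT_TO_OUTCOME.get(outcome_or_instrument, outcome_or_instrument)
    meta = INSTRUMENTS[key]
    items = np.asarray(items, dtype=float)
    if len(items) != meta["n_items"]:
        raise ScoreValidationError(
            f"{key}: expected {meta['n_items']} items, got {len(items)}"
        )
    lo, hi = meta["item_range"]
    if np.any(items < lo) or np.any(items > hi):
        raise ScoreValidationError(f"{key}: item responses outside [{lo}, {hi}]")
    return float(items.sum())


def dichotomize(outcome: str, period_average: float) -> int:
    """1 when the stay-at-home-period average meets the outcome's threshold
    (inclusive), else 0."""
    if pd.isna(period_average):
        raise ValueError(f"{outcome}: cannot dichotomize a missing average")
    return int(period_average >= INSTRUMENTS[outcome]["threshold"])


def build_outcomes(
    questionnaires: pd.DataFrame,
    period_boundary: datetime.date,
    study_end: datetime.date | None = None,
) -> pd.DataFrame:
    """Score every administration, average the stay-at-home-period
    administrations per participant, and dichotomize.

    ``questionnaires`` is the long item-level table
    (participant_id, date, instrument, item_index, value). Returns one row
    per (participant, outcome) with columns ``average`` and ``label``;
    participants without any stay-at-home administration of an instrument are
    absent for that outcome (missing label -> dropped downstream).
    """
    q = questionnaires.copy()
    q["date"] = pd.to_datetime(q["date"]).dt.date
    q["outcome"] = q["instrument"].map(INSTRUMENT_TO_OUTCOME)
    totals = (
        q.groupby(["participant_id", "outcome", "date"], observed=True)["value"]
        .sum()
        .reset_index(name="score")
    )
    for outcome in OUTCOMES:
        lo, hi = INSTRUMENTS[outcome]["score_range"]
        sub = totals.loc[totals["outcome"] == outcome, "score"]
        if len(sub) and (sub.min() < lo or sub.max() > hi):
            raise ScoreValidationError(f"{outcome}: administration total outside [{lo}, {hi}]")
    stay = totals[totals["date"] >= period_boundary]
    if study_end is not None:
        stay = stay[stay["date"] < study_end]
    avg = (
        stay.groupby(["participant_id", "outcome"], observed=True)["score"]
        .mean()
        .reset_index(name="average")
    )
    avg["label"] = [
        dichotomize(o, a) for o, a in zip(avg["outcome"], avg["average"])
    ]
    return avg


def outcome_correlations(averages: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (and two-sided p-values) among the four
    period-averaged outcomes.

    ``averages`` is wide: one row per participant, one column per outcome.
    Requires at least 3 participants with all four averages; a zero-variance
    outcome yields missing correlations.
    """
    cols = [o for o in OUTCOMES if o in averages.columns]
    data = averages[cols].dropna()
    if len(data) < 3:
        raise ValueError("outcome correlations need >= 3 complete participants")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = data[a].to_numpy(), data[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p
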