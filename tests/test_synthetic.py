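"""Synthetic cohort generator: calendar logic, determinism, missingness, and
the placement of planted behavior shifts."""

import datetime

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from mssense.constants import OUTCOMES
from mssense.outcomes import build_outcomes
from mssense.synthetic import (
    CohortConfig,
    ConfigurationError,
    MissingnessConfig,
    generate_cohort,
    inject_missingness,
    make_profiles,
)

from conftest import SMALL_DATES


def test_default_calendar_spans():
    cfg = CohortConfig(n_participants=1)
    assert cfg.study_start == datetime.date(2019, 11, 16)
    assert cfg.period_boundary == datetime.date(2020, 3, 23)
    assert cfg.n_pre_days == 128
    assert cfg.n_stay_days == 53


@pytest.mark.parametrize(
    "kwargs",
    [
        {"study_start": datetime.date(2020, 6, 1)},           # start after boundary
        {"period_boundary": datetime.date(2020, 6, 1)},       # boundary after end
        {"prevalence": {"depression": 1.5}},
        {"missingness": MissingnessConfig(daily_dropout=-0.1)},
        {"effect_size": {"depression": {"not_a_param": 1.0}}},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        CohortConfig(n_participants=2, **kwargs)


def test_identical_seed_gives_identical_cohort(small_config, small_cohort):
    again = generate_cohort(small_config)
    for pid, streams in small_cohort.streams.items():
        for sensor, df in streams.items():
            assert_frame_equal(df, again.streams[pid][sensor])
    assert_frame_equal(small_cohort.questionnaires, again.questionnaires)


def test_different_seed_differs(small_config):
    import dataclasses

    other = generate_cohort(dataclasses.replace(small_config, seed=small_config.seed + 1))
    df_a = next(iter(other.streams.values()))["heart"]
    df_b = next(iter(generate_cohort(small_config).streams.values()))["heart"]
    assert not df_a["bpm"].equals(df_b["bpm"])


def test_physiologic_and_schema_invariants(small_cohort):
    for streams in small_cohort.streams.values():
        hr = streams["heart"]["bpm"]
        assert hr.between(30, 220).all()
        assert (streams["steps"]["steps"] >= 0).all()
        assert streams["sleep"]["status"].isin(["asleep", "awake", "restless", "unknown"]).all()
        calls = streams["calls"]
        assert (calls["duration_s"] >= 0).all()
        assert (calls.loc[calls["call_type"] == "missed", "duration_s"] == 0).all()
        for df in streams.values():
            assert df["timestamp"].is_monotonic_increasing


def test_location_sampling_rate(small_cohort):
    loc = small_cohort.streams["p000"]["location"]
    gaps = loc["timestamp"].diff().dropna()
    assert (gaps >= pd.Timedelta(minutes=10)).all()


def test_stay_shift_leaves_pre_period_untouched(small_config):
    """With only stay-at-home shifts configured, pre-period behavior must be
    distributed identically across label groups (here: exact equality of the
    pre-period stream under an effects-on vs effects-off config)."""
    import dataclasses

    cfg_on = small_config
    cfg_off = dataclasses.replace(cfg_on, effect_size={})
    on = generate_cohort(cfg_on)
    off = generate_cohort(cfg_off)
    boundary = pd.Timestamp(cfg_on.period_boundary)
    for pid in on.streams:
        a = on.streams[pid]["heart"]
        b = off.streams[pid]["heart"]
        assert_frame_equal(
            a[a["timestamp"] < boundary].reset_index(drop=True),
            b[b["timestamp"] < boundary].reset_index(drop=True),
        )


def test_planted_shift_moves_stay_behavior():
    """A strong resting-heart-rate shift shows up in the stay period of
    positive participants and nowhere else."""
    cfg = CohortConfig(
        n_participants=20, seed=3,
        effect_size={"depression": {"resting_hr": 2.0}},
        prevalence={o: 0.5 for o in OUTCOMES},
        missingness=MissingnessConfig(daily_dropout=0, gap_rate=0, insufficient_fraction=0),
        **SMALL_DATES,
    )
    cohort = generate_cohort(cfg)
    boundary = pd.Timestamp(cfg.period_boundary)
    deltas = {}
    for prof in cohort.profiles:
        hr = cohort.streams[prof.participant_id]["heart"]
        pre = hr.loc[hr["timestamp"] < boundary, "bpm"].mean()
        stay = hr.loc[hr["timestamp"] >= boundary, "bpm"].mean()
        deltas[prof.participant_id] = (stay - pre, prof.labels["depression"])
    pos = [d for d, lab in deltas.values() if lab == 1]
    neg = [d for d, lab in deltas.values() if lab == 0]
    assert np.mean(pos) - np.mean(neg) > 5.0  # 2 SD = 10 bpm, minus mandate noise


def test_labels_consistent_with_questionnaires(small_cohort, small_config):
    table = build_outcomes(
        small_cohort.questionnaires, small_config.period_boundary, small_config.study_end
    )
    merged = table.merge(small_cohort.labels, on=["participant_id", "outcome"])
    assert (merged["label_x"] == merged["label_y"]).mean() >= 0.9


class TestInjectMissingness:
    def _steps_stream(self, n_days, cfg):
        t0 = pd.Timestamp(cfg.study_start)
        ts = t0 + pd.to_timedelta(np.arange(n_days), unit="D")
        return {"steps": pd.DataFrame({"timestamp": ts, "steps": np.ones(n_days)})}

    def test_zero_dropout_is_identity(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config,
            missingness=MissingnessConfig(daily_dropout=0, gap_rate=0, insufficient_fraction=0),
        )
        streams = self._steps_stream(20, cfg)
        out = inject_missingness(streams, cfg, np.random.default_rng(0))
        assert_frame_equal(out["steps"], streams["steps"])

    def test_total_dropout_empties_sensor(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config,
            missingness=MissingnessConfig(daily_dropout=1.0, gap_rate=0, insufficient_fraction=0),
        )
        out = inject_missingness(self._steps_stream(20, cfg), cfg, np.random.default_rng(0))
        assert out["steps"].empty

    def test_dropout_rate_matches_binomial_expectation(self, small_config):
        """Daily dropout 0.2 over 10,000 sensor-days loses 20% +/- 1 point."""
        import dataclasses

        cfg = dataclasses.replace(
            small_config,
            study_start=datetime.date(2000, 1, 1),
            period_boundary=datetime.date(2010, 1, 1),
            study_end=datetime.date(2030, 1, 1),
            missingness=MissingnessConfig(daily_dropout=0.2, gap_rate=0, insufficient_fraction=0),
        )
        streams = self._steps_stream(10_000, cfg)
        out = inject_missingness(streams, cfg, np.random.default_rng(1))
        frac = 1 - len(out["steps"]) / 10_000
        assert abs(frac - 0.2) < 0.01

    def test_insufficient_pre_period_strips_pre_data(self, small_config):
        streams = self._steps_stream(40, small_config)
        out = inject_missingness(
            streams, small_config, np.random.default_rng(0), insufficient_pre=True
        )
        boundary = pd.Timestamp(small_config.period_boundary)
        pre = out["steps"][out["steps"]["timestamp"] < boundary]
        assert len(pre) <= 1
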