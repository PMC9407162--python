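"""Daily feature definitions, period averaging, and behavior-change deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mssense.features import (
    FEATURE_CATALOG,
    FeatureConfig,
    behavior_change,
    daily_features,
    feature_keys,
    haversine_m,
    period_average,
    place_entropy_bits,
    screen_episodes,
)

CFG = FeatureConfig()


def _loc_df(points, start="2020-01-06 08:00:00", step_min=10):
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(points)) * step_min, unit="min")
    lat, lon = zip(*points)
    return pd.DataFrame({"timestamp": ts, "lat": lat, "lon": lon})


class TestLocationFeatures:
    def test_stationary_day(self):
        df = _loc_df([(40.44, -79.99)] * 12)
        out = daily_features("location", df, CFG)
        assert out["total_distance_m"] == 0.0
        assert out["n_places"] == 1
        assert out["entropy_bits"] == 0.0
        assert out["normalized_entropy"] == 0.0
        assert out["time_at_home_fraction"] == 1.0
        assert out["radius_of_gyration_m"] == pytest.approx(0.0, abs=1e-6)

    def test_two_places_equal_dwell_entropy_one_bit(self):
        # half the day at each of two far-apart places
        a, b = (40.44, -79.99), (40.47, -79.95)
        df = _loc_df([a] * 6 + [b] * 6)
        out = daily_features("location", df, CFG)
        assert out["n_places"] == 2
        assert out["entropy_bits"] == pytest.approx(1.0)
        assert out["normalized_entropy"] == pytest.approx(1.0)

    def test_entropy_bounded_by_log_places(self):
        rng = np.random.default_rng(0)
        places = [(40.44 + 0.01 * k, -79.99) for k in range(4)]
        pts = [places[i] for i in rng.integers(0, 4, 48)]
        out = daily_features("location", _loc_df(pts), CFG)
        if out["n_places"] > 1:
            assert out["entropy_bits"] <= np.log2(out["n_places"]) + 1e-9
            assert 0.0 <= out["normalized_entropy"] <= 1.0

    def test_radius_of_gyration_zero_iff_coincident(self):
        same = daily_features("location", _loc_df([(40.44, -79.99)] * 5), CFG)
        moved = daily_features(
            "location", _loc_df([(40.44, -79.99)] * 5 + [(40.45, -79.99)] * 5), CFG
        )
        assert same["radius_of_gyration_m"] == pytest.approx(0.0, abs=1e-6)
        assert moved["radius_of_gyration_m"] > 100.0

    def test_haversine_known_distance(self):
        # one degree of latitude is ~111.2 km
        d = haversine_m(np.array([40.0]), np.array([-80.0]), np.array([41.0]), np.array([-80.0]))
        assert d[0] == pytest.approx(111_195, rel=0.01)


class TestHeartFeatures:
    def test_constant_sixty_bpm_age_forty(self):
        ts = pd.date_range("2020-01-06 00:00", periods=100, freq="min")
        df = pd.DataFrame({"timestamp": ts, "bpm": 60})
        out = daily_features("heart", df, FeatureConfig(age_years=40))
        assert out["mean_bpm"] == 60
        assert out["std_bpm"] == 0
        assert out["nonexercise_mean_bpm"] == 60  # zone boundary = 90 bpm
        assert out["exercise_fraction"] == 0.0

    def test_exercise_fraction_counts_zone_minutes(self):
        ts = pd.date_range("2020-01-06 00:00", periods=10, freq="min")
        df = pd.DataFrame({"timestamp": ts, "bpm": [60] * 8 + [150, 150]})
        out = daily_features("heart", df, FeatureConfig(age_years=40))
        assert out["exercise_fraction"] == pytest.approx(0.2)
        assert out["nonexercise_mean_bpm"] == 60
        assert out["max_bpm"] == 150


class TestSleepFeatures:
    def test_interrupted_night(self):
        # 360 asleep minutes with two 5-minute awake interruptions
        statuses = (["asleep"] * 120 + ["awake"] * 5 + ["asleep"] * 120
                    + ["awake"] * 5 + ["asleep"] * 120)
        ts = pd.Timestamp("2020-01-06 00:30") + pd.to_timedelta(
            np.arange(len(statuses)), unit="min"
        )
        df = pd.DataFrame({"timestamp": ts, "status": statuses})
        out = daily_features("sleep", df, CFG)
        assert out["asleep_min"] == 360
        assert out["awake_min"] == 10
        assert out["n_awakenings"] == 2
        assert out["sleep_efficiency"] == pytest.approx(360 / 370)
        assert out["onset_min_after_midnight"] == 30
        assert out["offset_min_after_midnight"] == 30 + 370

    def test_empty_sleep_day_is_missing(self):
        out = daily_features("sleep", pd.DataFrame(columns=["timestamp", "status"]), CFG)
        assert all(np.isnan(v) for v in out.values())


class TestStepsFeatures:
    def test_active_minutes_streaks_and_sedentary_bouts(self):
        # 40 sedentary minutes, 10 active, 35 sedentary
        steps = [0] * 40 + [80] * 10 + [2] * 35
        ts = pd.Timestamp("2020-01-06 10:00") + pd.to_timedelta(np.arange(85), unit="min")
        df = pd.DataFrame({"timestamp": ts, "steps": steps})
        out = daily_features("steps", df, CFG)
        assert out["total_steps"] == sum(steps)
        assert out["active_min"] == 10
        assert out["max_active_streak_min"] == 10
        assert out["sedentary_bout_count"] == 2  # runs of 40 and 35 minutes

    def test_gap_breaks_runs(self):
        ts = list(pd.date_range("2020-01-06 10:00", periods=20, freq="min"))
        ts += list(pd.date_range("2020-01-06 12:00", periods=20, freq="min"))
        df = pd.DataFrame({"timestamp": ts, "steps": [0] * 40})
        out = daily_features("steps", df, FeatureConfig(sedentary_bout_min=15))
        assert out["sedentary_bout_count"] == 2


class TestCallsAndScreen:
    def test_call_counts_and_durations(self):
        df = pd.DataFrame({
            "timestamp": pd.to_datetime([
                "2020-01-06T09:00:00", "2020-01-06T10:00:00",
                "2020-01-06T11:00:00", "2020-01-06T12:00:00",
            ]),
            "call_type": ["incoming", "outgoing", "missed", "incoming"],
            "duration_s": [60.0, 120.0, 0.0, 30.0],
        })
        out = daily_features("calls", df, CFG)
        assert out["n_incoming"] == 2
        assert out["n_outgoing"] == 1
        assert out["n_missed"] == 1
        assert out["total_duration_incoming_s"] == 90
        assert out["total_duration_outgoing_s"] == 120
        assert out["mean_duration_s"] == pytest.approx(210 / 3)

    def test_empty_event_day_zero_fills_counts_only(self):
        out = daily_features("calls", pd.DataFrame(columns=["timestamp", "call_type", "duration_s"]),
                             CFG, phone_alive=True)
        assert out["n_incoming"] == 0
        assert np.isnan(out["mean_duration_s"])

    def test_screen_episode_pairing(self):
        df = pd.DataFrame({
            "timestamp": pd.to_datetime([
                "2020-01-06T09:00:00", "2020-01-06T09:04:00",
                "2020-01-06T10:00:00", "2020-01-06T10:01:30",
            ]),
            "event": ["unlock", "off", "unlock", "lock"],
        })
        eps = screen_episodes(df)
        assert len(eps) == 2
        assert eps["duration_min"].tolist() == [4.0, 1.5]
        out = daily_features("screen", df, CFG)
        assert out["n_unlock_episodes"] == 2
        assert out["total_interaction_min"] == pytest.approx(5.5)
        assert out["max_episode_min"] == 4.0


class TestPeriodAveraging:
    PERIOD = (pd.Timestamp("2020-01-06").date(), pd.Timestamp("2020-02-03").date())

    def _rows(self, values, start="2020-01-06"):
        dates = pd.date_range(start, periods=len(values), freq="D")
        return pd.DataFrame({"date": dates, "f": values})

    def test_single_day_identity(self):
        assert period_average(self._rows([4.0]), self.PERIOD)["f"] == 4.0

    def test_two_day_mean(self):
        assert period_average(self._rows([2.0, 4.0]), self.PERIOD)["f"] == 3.0

    def test_matches_brute_force_mean_and_shuffle_invariant(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=28)
        rows = self._rows(vals)
        avg = period_average(rows, self.PERIOD)["f"]
        assert avg == pytest.approx(np.mean(vals))
        shuffled = rows.sample(frac=1, random_state=0)
        assert period_average(shuffled, self.PERIOD)["f"] == pytest.approx(avg)

    def test_dayset_restriction(self):
        rows = self._rows(np.arange(14.0))
        weekdays = period_average(rows, self.PERIOD, "weekdays")["f"]
        brute = rows[rows["date"].dt.dayofweek < 5]["f"].mean()
        assert weekdays == pytest.approx(brute)

    def test_outside_period_is_missing(self):
        rows = self._rows([1.0], start="2021-06-01")
        assert np.isnan(period_average(rows, self.PERIOD)["f"])


class TestBehaviorChange:
    def test_identical_periods_give_exact_zero(self):
        x = pd.Series({"a": 1.23, "b": -9.7})
        assert (behavior_change(x, x) == 0).all()

    def test_signed_difference(self):
        pre = pd.Series({"a": 2.0})
        stay = pd.Series({"a": 5.0})
        assert behavior_change(pre, stay)["a"] == 3.0

    def test_key_mismatch_raises(self):
        with pytest.raises(ValueError, match="keys"):
            behavior_change(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=8))
    def test_self_delta_zero_property(self, vals):
        x = pd.Series(vals)
        assert (behavior_change(x, x) == 0).all()


class TestCatalog:
    def test_calls_matrix_has_ninety_columns(self):
        assert len(feature_keys("calls")) == 6 * 15 == 90

    def test_total_key_count(self):
        per_slice = sum(len(v) for v in FEATURE_CATALOG.values())
        total = sum(len(feature_keys(s)) for s in FEATURE_CATALOG)
        assert total == per_slice * 15

    def test_entropy_helper(self):
        assert place_entropy_bits(np.array([6, 6])) == pytest.approx(1.0)
        assert place_entropy_bits(np.array([10])) == 0.0
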