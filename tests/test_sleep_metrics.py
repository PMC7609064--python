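import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flysleep.dam_io import ActivityRecording, LightSchedule, TemperatureEpoch, zt_minutes
from flysleep.sleep_metrics import (
    flag_dead,
    nightly_sleep,
    score_sleep,
    sleep_change,
    sleep_summary_frame,
    summarize,
    tukey_box_summary,
)

from .oracles import brute_force_bouts

START = dt.datetime(2021, 1, 1, 8, 0)


class TestScoreSleep:
    def test_five_minute_rule_worked_example(self):
        """Leading 5-zero run is one bout; the trailing 4-zero run is not
        sleep (inactivity must last at least 5 min)."""
        s = score_sleep(np.array([0, 0, 0, 0, 0, 3, 0, 0, 0, 0]))
        assert [(b.start_minute, b.duration_min) for b in s.bouts] == [(0, 5)]
        assert s.total_sleep_min == 5

    def test_always_active_has_no_sleep(self):
        s = score_sleep(np.ones(100, dtype=int))
        assert s.bouts == [] and s.total_sleep_min == 0

    def test_boundary_runs_count_at_observed_length(self):
        s = score_sleep(np.array([1] + [0] * 5))
        assert [(b.start_minute, b.duration_min) for b in s.bouts] == [(1, 5)]

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            v = (rng.random(1440) < rng.uniform(0.2, 0.9)).astype(int)
            got = [(b.start_minute, b.duration_min) for b in score_sleep(v).bouts]
            assert got == brute_force_bouts(v)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=120), st.data())
    def test_monotone_in_activity(self, counts, data):
        """Waking any sleeping minute (zero -> positive) never adds sleep."""
        v = np.array(counts)
        before = score_sleep(v).total_sleep_min
        zeros = np.flatnonzero(v == 0)
        if len(zeros) == 0:
            return
        idx = data.draw(st.sampled_from(list(zeros)))
        v[idx] = 1
        assert score_sleep(v).total_sleep_min <= before

    def test_bout_minutes_partition_asleep_minutes(self, rng):
        v = (rng.random(2000) < 0.5).astype(int)
        s = score_sleep(v)
        assert sum(b.duration_min for b in s.bouts) == s.total_sleep_min
        rebuilt = np.zeros(len(v), dtype=bool)
        for b in s.bouts:
            assert (v[b.start_minute : b.end_minute] == 0).all()
            rebuilt[b.start_minute : b.end_minute] = True
        np.testing.assert_array_equal(rebuilt, s.asleep)

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            score_sleep(np.array([], dtype=int))


class TestSummarize:
    def _zt(self, n):
        return np.arange(n) % 1440

    def test_bout_spanning_dusk_splits_by_minute_membership(self):
        v = np.ones(1440, dtype=int)
        v[716:730] = 0  # 14-min bout over the ZT720 day/night boundary
        s = score_sleep(v)
        summ = summarize(s, self._zt(1440))
        assert summ.daytime_sleep_min == 4
        assert summ.nighttime_sleep_min == 10
        assert summ.total_sleep_min == 14

    def test_full_night_saturates(self):
        v = np.ones(1440, dtype=int)
        v[720:] = 0
        summ = summarize(score_sleep(v), self._zt(1440))
        assert summ.nighttime_sleep_min == 720
        assert (summ.profile_30min[24:] == 30).all()

    def test_conservation_on_random_series(self, rng):
        for _ in range(25):
            v = (rng.random(2880) < 0.5).astype(int)
            s = score_sleep(v)
            summ = summarize(s, self._zt(2880), (1440, 2880))
            direct = int(s.asleep[1440:2880].sum())
            assert summ.total_sleep_min == direct
            assert summ.daytime_sleep_min + summ.nighttime_sleep_min == direct
            assert int(summ.profile_30min.sum()) == direct
            assert (summ.profile_30min <= 30).all()

    def test_uncovered_window_rejected(self):
        s = score_sleep(np.ones(1000, dtype=int))
        with pytest.raises(ValueError):
            summarize(s, self._zt(1000), (0, 1440))

    def test_nightly_sleep_counts_full_nights_only(self):
        v = np.ones(2160, dtype=int)  # 1.5 days: one full night then half day
        v[720:1440] = 0
        s = score_sleep(v)
        assert nightly_sleep(s, self._zt(2160)).tolist() == [720]


class TestSleepChange:
    SCHEDULE = [
        TemperatureEpoch("baseline", 0, 2160, 22.0),
        TemperatureEpoch("activation", 2160, 3600, 29.0),
        TemperatureEpoch("recovery", 3600, 5040, 22.0),
    ]

    def _series(self, base_night_sleep, act_night_sleep):
        v = np.ones(5040, dtype=int)
        v[720 : 720 + base_night_sleep] = 0  # baseline night (ZT720-1440)
        v[2160 : 2160 + act_night_sleep] = 0  # activation night
        zt = np.arange(5040) % 1440
        return score_sleep(v), zt

    def test_delta_is_activation_minus_baseline(self):
        s, zt = self._series(420, 300)
        change = sleep_change(s, zt, self.SCHEDULE)
        assert change.baseline_sleep_min == 420
        assert change.activation_sleep_min == 300
        assert change.delta_min == -120

    def test_identical_behavior_gives_zero_delta(self):
        s, zt = self._series(400, 400)
        assert sleep_change(s, zt, self.SCHEDULE).delta_min == 0

    def test_missing_instance_rejected(self):
        s, zt = self._series(400, 400)
        with pytest.raises(ValueError, match="absent"):
            sleep_change(s, zt, self.SCHEDULE, activation_ordinal=2)


class TestFlagDead:
    def _rec(self, minutes):
        return ActivityRecording("a", 1, minutes, START)

    def test_active_fly_alive(self, rng):
        dead, _ = flag_dead(self._rec(rng.poisson(2, 2880) + 1))
        assert not dead

    def test_terminal_13h_inactivity_is_dead(self):
        v = np.ones(2880, dtype=int)
        v[-13 * 60 :] = 0
        dead, death_minute = flag_dead(self._rec(v))
        assert dead and death_minute == 2880 - 13 * 60

    def test_terminal_11p5h_inactivity_is_alive(self):
        v = np.ones(2880, dtype=int)
        v[-690:] = 0
        dead, death_minute = flag_dead(self._rec(v))
        assert not dead and death_minute is None


class TestTukeyBox:
    def test_one_to_nine(self):
        """Quartiles by linear interpolation between order statistics."""
        box = tukey_box_summary(range(1, 10))
        assert (box.q1, box.median, box.q3) == (3.0, 5.0, 7.0)
        assert (box.whisker_low, box.whisker_high) == (1.0, 9.0)
        assert box.outliers.size == 0

    def test_all_equal(self):
        box = tukey_box_summary([4.0] * 6)
        assert box.q1 == box.q3 == box.whisker_low == box.whisker_high == 4.0
        assert box.outliers.size == 0

    def test_outlier_detection(self):
        # sorted oracle: Q1=2, Q3=4, IQR=2 -> fences [-1, 7]; 100 is outside
        box = tukey_box_summary([1, 2, 3, 4, 100])
        assert box.outliers.tolist() == [100]
        assert box.whisker_high == 4.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tukey_box_summary([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_whiskers_bracket_non_outliers(self, values):
        box = tukey_box_summary(values)
        v = np.array(values)
        inside = v[(v >= box.whisker_low) & (v <= box.whisker_high)]
        assert len(inside) + box.outliers.size == len(v)
        assert box.whisker_low <= box.q1 + 1e-9
        assert box.whisker_high >= box.q3 - 1e-9


def test_summary_frame_schema(rng):
    rec = ActivityRecording("f1", 1, (rng.random(1440) < 0.5).astype(int),
                            START, condition={"diet": "fed"})
    s = score_sleep(rec)
    zt = zt_minutes(rec, LightSchedule())
    df = sleep_summary_frame([(rec, s, summarize(s, zt))])
    assert list(df.columns) == [
        "fly_id", "diet", "daytime_sleep_min", "nighttime_sleep_min",
        "total_sleep_min", "n_bouts", "mean_bout_len",
    ]
    assert df.loc[0, "fly_id"] == "f1"
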