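import json

import numpy as np
import pytest

from flysleep.dam_io import LightSchedule, read_monitor_file, zt_minutes
from flysleep.simulate import (
    EpochOverride,
    FlyModel,
    build_experiment,
    calibrate_night_p_wake,
    expected_scored_sleep,
    expected_scored_sleep_stationary,
    models_for_targets,
    scored_run_fraction,
    simulate_cohort,
    simulate_fly,
    simulate_gcamp,
    simulate_latency_trials,
    simulate_multibeam,
    stationary_sleep_fraction,
)
from flysleep.sleep_metrics import score_sleep, summarize

from .oracles import brute_force_scored_minutes, enumerate_expected_scored_sleep


class TestDeterminism:
    def test_same_seed_identical_recording(self):
        a, ta = simulate_fly(FlyModel(seed=11), 1)
        b, tb = simulate_fly(FlyModel(seed=11), 1)
        np.testing.assert_array_equal(a.minutes, b.minutes)
        np.testing.assert_array_equal(ta.states, tb.states)

    def test_different_fly_ids_differ(self):
        a, _ = simulate_fly(FlyModel(seed=11), 1, fly_id="x")
        b, _ = simulate_fly(FlyModel(seed=11), 1, fly_id="y")
        assert not np.array_equal(a.minutes, b.minutes)

    def test_cohort_matches_single_fly_calls(self):
        models = [FlyModel(seed=4), FlyModel(seed=4, p_wake_night=0.08)]
        together = simulate_cohort(models, 1, fly_ids=["a", "b"])
        for model, fid, (rec, _) in zip(models, ["a", "b"], together):
            alone, _ = simulate_fly(model, 1, fly_id=fid)
            np.testing.assert_array_equal(rec.minutes, alone.minutes)

    def test_gcamp_deterministic(self):
        t1, _ = simulate_gcamp(seed=9)
        t2, _ = simulate_gcamp(seed=9)
        np.testing.assert_array_equal(t1.raw_F, t2.raw_F)


class TestChainBehavior:
    def test_near_certain_waking_yields_no_scored_sleep(self):
        model = FlyModel(
            p_fall_asleep_day=1e-5, p_fall_asleep_night=1e-5,
            p_wake_day=0.999, p_wake_night=0.999, seed=2,
        )
        rec, truth = simulate_fly(model, 2)
        assert score_sleep(rec).total_sleep_min == 0
        assert truth.states.sum() < 50  # the rare sleep minutes are isolated

    def test_awake_minutes_always_emit_counts(self):
        rec, truth = simulate_fly(FlyModel(seed=3), 2)
        assert (rec.minutes[~truth.states] >= 1).all()
        assert (rec.minutes[truth.states] == 0).all()

    def test_emission_mean_matches_configured_rate(self):
        model = FlyModel(seed=5, wake_activity_rate=2.5)
        rec, truth = simulate_fly(model, 4)
        awake_counts = rec.minutes[~truth.states]
        se = awake_counts.std() / np.sqrt(len(awake_counts))
        assert abs(awake_counts.mean() - 2.5) < 4 * se

    def test_symmetric_chain_long_run_fraction_and_scored_sleep(self):
        """p_fall = p_wake = 0.1 around the clock: the sleep-state fraction
        approaches 1/2 and scored sleep matches the geometric run-length
        expectation pi * q^4 (5(1-q) + q)."""
        model = FlyModel(
            p_fall_asleep_day=0.1, p_fall_asleep_night=0.1,
            p_wake_day=0.1, p_wake_night=0.1, seed=6,
        )
        results = simulate_cohort([model] * 80, 2,
                                  fly_ids=[f"f{i}" for i in range(80)])
        frac_state = np.mean([t.states.mean() for _, t in results])
        assert frac_state == pytest.approx(0.5, abs=0.02)
        scored = np.mean(
            [score_sleep(rec).total_sleep_min / len(rec) for rec, _ in results]
        )
        expected = stationary_sleep_fraction(0.1, 0.1) * scored_run_fraction(0.1)
        assert scored == pytest.approx(expected, abs=0.02)

    def test_scored_sleep_never_exceeds_true_state_minutes(self):
        for seed in range(5):
            rec, truth = simulate_fly(FlyModel(seed=seed), 1)
            assert score_sleep(rec).total_sleep_min <= truth.states.sum()


class TestExpectedScoredSleep:
    def test_exact_dp_matches_full_enumeration(self, rng):
        """DP expectation equals brute-force enumeration over all 2^n
        hidden-state sequences for arbitrary inhomogeneous chains."""
        for trial in range(6):
            n = int(rng.integers(6, 11))
            p_fall = rng.uniform(0.05, 0.6, n)
            p_wake = rng.uniform(0.05, 0.6, n)
            init = float(rng.uniform(0, 1))
            min_bout = int(rng.integers(2, 5))
            got = expected_scored_sleep(p_fall, p_wake, min_bout=min_bout,
                                        init_p_sleep=init)
            want = enumerate_expected_scored_sleep(
                p_fall, p_wake, init_p_sleep=init, min_bout=min_bout
            )
            assert got == pytest.approx(want, rel=1e-10)

    def test_dp_approaches_stationary_formula_on_long_homogeneous_chain(self):
        n = 20000
        p_fall, p_wake = np.full(n, 0.08), np.full(n, 0.05)
        dp = expected_scored_sleep(p_fall, p_wake)
        stat = expected_scored_sleep_stationary(0.08, 0.05, n)
        assert dp == pytest.approx(stat, rel=0.005)

    def test_window_argument_sums_subrange(self):
        n = 200
        p_fall, p_wake = np.full(n, 0.1), np.full(n, 0.1)
        whole = expected_scored_sleep(p_fall, p_wake)
        left = expected_scored_sleep(p_fall, p_wake, window=(0, 100))
        right = expected_scored_sleep(p_fall, p_wake, window=(100, n))
        assert whole == pytest.approx(left + right)


class TestCalibration:
    def test_calibrated_cohort_hits_target_mean(self):
        target = 420.0
        pw = calibrate_night_p_wake(target)
        model = FlyModel(p_wake_night=pw, seed=8)
        results = simulate_cohort([model] * 120, 1,
                                  fly_ids=[f"f{i}" for i in range(120)])
        nights = []
        for rec, _ in results:
            zt = zt_minutes(rec, LightSchedule())
            nights.append(summarize(score_sleep(rec), zt).nighttime_sleep_min)
        assert np.mean(nights) == pytest.approx(target, abs=15)

    def test_models_for_targets_labels_and_spread(self):
        cells = [({"diet": "fed"}, 300.0), ({"diet": "deprived"}, 500.0)]
        models, fly_ids = models_for_targets(cells, 10, seed=1)
        assert len(models) == 20 and len(set(fly_ids)) == 20
        assert {m.condition["diet"] for m in models} == {"fed", "deprived"}
        # heterogeneity: calibrated waking probabilities differ across flies
        assert len({m.p_wake_night for m in models}) > 15


class TestMultibeam:
    def test_counts_dominate_moves_everywhere(self):
        mv, ct, _ = simulate_multibeam(FlyModel(seed=10), 2)
        assert (ct.minutes >= mv.minutes).all()

    def test_degenerate_no_micro_no_twitch_makes_modes_equal(self):
        mv, ct, _ = simulate_multibeam(
            FlyModel(seed=10), 1, micro_rate=0.0, twitch_prob=0.0
        )
        np.testing.assert_array_equal(mv.minutes, ct.minutes)

    def test_awake_fly_pacing_registers_moves(self):
        mv, _, truth = simulate_multibeam(FlyModel(seed=12), 1, move_rate=3.0)
        awake = ~truth.states
        assert mv.minutes[awake].mean() > 1.0

    def test_counts_mode_scores_no_more_sleep_than_moves_mode(self):
        for seed in range(12):
            mv, ct, _ = simulate_multibeam(FlyModel(seed=seed), 1,
                                           twitch_prob=0.15)
            assert (
                score_sleep(ct).total_sleep_min
                <= score_sleep(mv).total_sleep_min
            )


class TestLatencyTrials:
    def test_zero_rate_censors_everything(self):
        trials = simulate_latency_trials(0.0, 0.0, 8, seed=1)
        assert all(t.t_court_init is None for t in trials)

    def test_event_times_precede_censor_horizon(self):
        trials = simulate_latency_trials(1 / 600, 1 / 900, 50, seed=2)
        for t in trials:
            if t.t_court_init is not None:
                assert 0 < t.t_court_init < 7200
            if t.t_copulation is not None:
                assert t.t_copulation < 7200

    def test_deterministic(self):
        a = simulate_latency_trials(1 / 600, 1 / 900, 5, seed=3)
        b = simulate_latency_trials(1 / 600, 1 / 900, 5, seed=3)
        assert [t.t_court_init for t in a] == [t.t_court_init for t in b]


class TestBuildExperiment:
    def test_fig1_preset_layout(self, tmp_path):
        manifest = build_experiment(
            {"preset": "fig1_nutrition_by_pairing", "n_per_cell": 3,
             "seed": 5, "n_days": 1},
            tmp_path,
        )
        recs = [
            r for f in manifest["monitor_files"] for r in read_monitor_file(f)
        ]
        assert len(recs) == 12
        truth = json.loads((tmp_path / "truth.json").read_text())
        conds = {
            (f["condition"]["sex_pairing"], f["condition"]["diet"])
            for f in truth["flies"]
        }
        assert conds == {("MM", "fed"), ("MF", "fed"),
                         ("MM", "deprived"), ("MF", "deprived")}

    def test_fig7_preset_plants_hits(self, tmp_path):
        manifest = build_experiment(
            {"preset": "fig7_screen", "n_per_line": 2, "n_lines": 4,
             "hit_lines": (2,), "seed": 5},
            tmp_path,
        )
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["hit_lines"] == ["L02"]
        groups = {f["condition"]["group"] for f in truth["flies"]}
        assert groups == {"experimental", "gal4_control", "uas_control"}

    def test_zero_fly_config_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_experiment(
                {"preset": "fig1_nutrition_by_pairing", "n_per_cell": 0},
                tmp_path,
            )

    def test_unknown_preset_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="preset"):
            build_experiment({"preset": "nope"}, tmp_path)


def test_epoch_override_changes_only_its_span():
    model = FlyModel(seed=14)
    override = EpochOverride(2160, 2880, p_wake_night=0.5)  # night of day 2
    base, _ = simulate_fly(model, 2)
    mod, _ = simulate_fly(model, 2, overrides=[override])
    np.testing.assert_array_equal(base.minutes[:2160], mod.minutes[:2160])
    assert not np.array_equal(base.minutes[2160:2880], mod.minutes[2160:2880])
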