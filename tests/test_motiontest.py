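import numpy as np
import pytest

from emgpr.motiontest import (
    MotionTestConfig,
    MotionTestResult,
    PredictionStream,
    cumulative_completion_curve,
    evaluate_trial,
    realtime_accuracy,
    run_motion_test,
    scripted_stream,
    selection_time,
)

CFG = MotionTestConfig()
REST = "rest"
M = "knee_flexion"


def stream_of(labels, prompted=M, config=CFG):
    return scripted_stream(prompted, labels, config)


class TestConfig:
    def test_first_event_at_211ms(self):
        assert CFG.first_event_ms == 211.0
        assert CFG.latency_offset_s == 0.211

    def test_timeout_below_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            MotionTestConfig(timeout_s=1.0)

    def test_required_correct_positive(self):
        with pytest.raises(ValueError):
            MotionTestConfig(required_correct=0)


class TestStreamTiming:
    def test_event_times(self):
        s = stream_of([M] * 3)
        times = [t for t, _ in s.events]
        assert times == [211.0, 261.0, 311.0]


class TestSelectionTime:
    def test_immediately_correct_hits_floor(self):
        s = stream_of([M] * 20)
        assert selection_time(s, CFG) == pytest.approx(0.211)

    def test_all_rest_undefined(self):
        s = stream_of([REST] * 50)
        assert selection_time(s, CFG) is None

    def test_wrong_then_correct(self):
        # first non-rest (wrong) at 211 ms, first correct at 411 ms
        s = stream_of(["other"] * 4 + [M] * 20)
        assert selection_time(s, CFG) == pytest.approx(0.200 + 0.211)

    def test_rest_prefix_does_not_shift_selection(self):
        # metrics measure from first non-rest; leading rest only burns clock
        s1 = stream_of([M] * 20)
        s2 = stream_of([REST] * 5 + [M] * 20)
        assert selection_time(s1, CFG) == selection_time(s2, CFG)


class TestRealtimeAccuracy:
    def test_20_of_25_is_80_percent(self):
        labels = [M] * 19 + ["other"] * 5 + [M]  # 25th prediction is 20th correct
        s = stream_of(labels)
        assert realtime_accuracy(s, CFG) == pytest.approx(0.80)

    def test_perfect_is_100_percent(self):
        s = stream_of([M] * 20)
        assert realtime_accuracy(s, CFG) == pytest.approx(1.0)

    def test_20_of_40_is_50_percent(self):
        labels = ["other", M] * 20  # 40th prediction is the 20th correct
        s = stream_of(labels)
        assert realtime_accuracy(s, CFG) == pytest.approx(0.50)

    def test_uncompleted_trial_rejected(self):
        s = stream_of(["other"] * 30)
        with pytest.raises(ValueError, match="completed"):
            realtime_accuracy(s, CFG)


class TestEvaluateTrial:
    def test_always_correct_floors(self):
        trial = evaluate_trial(stream_of([M] * 30), CFG)
        assert trial.completed
        assert trial.selection_time_s == pytest.approx(0.211)
        assert trial.completion_time_s == pytest.approx(1.161)
        assert round(trial.completion_time_s, 2) == 1.16
        assert trial.realtime_accuracy == pytest.approx(1.0)
        assert trial.predictions_to_completion == 20

    def test_never_correct_not_completed(self):
        trial = evaluate_trial(stream_of(["other"] * 100), CFG)
        assert not trial.completed
        assert trial.selection_time_s is None
        assert trial.completion_time_s is None
        assert trial.realtime_accuracy is None

    def test_timeout_enforced(self):
        # 20th correct would land after the 10 s timeout
        labels = [REST] * 190 + [M] * 25
        trial = evaluate_trial(stream_of(labels), CFG)
        assert not trial.completed

    def test_completion_just_inside_timeout(self):
        # event times: 211 + 50*i; event index 195 is at 9961 ms <= 10000
        labels = [REST] * 176 + [M] * 20
        trial = evaluate_trial(stream_of(labels), CFG)
        assert trial.completed


class TestFloorsProperty:
    def test_floors_across_randomized_streams(self, rng):
        """No completed trial beats the 0.211 s / 1.16 s floors."""
        classes = [M, "other", REST]
        for _ in range(200):
            labels = list(rng.choice(classes, size=rng.integers(20, 180),
                                     p=[0.5, 0.3, 0.2]))
            trial = evaluate_trial(stream_of(labels), CFG)
            if trial.completed:
                assert trial.selection_time_s >= 0.211 - 1e-12
                assert trial.completion_time_s >= 1.161 - 1e-12
                assert trial.completion_time_s >= trial.selection_time_s
                assert 0.0 < trial.realtime_accuracy <= 1.0
                k = trial.predictions_to_completion
                assert trial.realtime_accuracy == pytest.approx(20 / k)
                assert k >= 20

    def test_completion_selection_arithmetic(self, rng):
        """completion - selection == (#events between first correct and
        completing one) * increment, replayed brute force."""
        classes = [M, "other", REST]
        for _ in range(100):
            labels = list(rng.choice(classes, size=150, p=[0.4, 0.4, 0.2]))
            s = stream_of(labels)
            trial = evaluate_trial(s, CFG)
            if not trial.completed:
                continue
            # brute-force replay
            nonrest = [i for i, l in enumerate(labels) if l != REST]
            correct = [i for i, l in enumerate(labels) if l == M]
            i_complete = correct[19]
            gap_events = i_complete - correct[0]
            assert trial.completion_time_s - trial.selection_time_s == pytest.approx(
                gap_events * 0.050
            )


class TestAggregatesAndCurve:
    def _mixed_result(self):
        trials = [
            evaluate_trial(stream_of([M] * 30), CFG),                 # 1.161 s
            evaluate_trial(stream_of([REST] * 4 + [M] * 30), CFG),    # 1.161 s
            evaluate_trial(stream_of([M, "o"] * 25), CFG),            # slower
            evaluate_trial(stream_of(["o"] * 100), CFG),              # fails
        ]
        return MotionTestResult(trials=trials, config=CFG)

    def test_completion_percentage(self):
        res = self._mixed_result()
        assert res.completion_percentage == pytest.approx(75.0)

    def test_aggregates_exclude_uncompleted(self):
        res = self._mixed_result()
        agg = res.aggregates()
        sel = [t.selection_time_s for t in res.trials if t.completed]
        assert agg["selection_time_s"]["mean"] == pytest.approx(np.mean(sel))

    def test_curve_single_step(self):
        trials = [evaluate_trial(stream_of([M] * 30), CFG) for _ in range(4)]
        res = MotionTestResult(trials=trials, config=CFG)
        times, fracs = cumulative_completion_curve(res)
        assert times[0] == 0.0 and fracs[0] == 0.0
        assert fracs[-1] == 1.0
        assert all(t == pytest.approx(1.161) for t in times[1:])

    def test_curve_no_completions_constant_zero(self):
        trials = [evaluate_trial(stream_of(["o"] * 50), CFG)]
        res = MotionTestResult(trials=trials, config=CFG)
        times, fracs = cumulative_completion_curve(res)
        assert list(fracs) == [0.0]

    def test_curve_equals_empirical_cdf(self):
        res = self._mixed_result()
        times, fracs = cumulative_completion_curve(res)
        comp = sorted(t.completion_time_s for t in res.trials if t.completed)
        assert np.all(np.diff(fracs) >= 0)
        assert fracs[-1] == pytest.approx(res.completion_percentage / 100.0)
        np.testing.assert_allclose(times[1:], comp)

    def test_report_files(self, tmp_path):
        res = self._mixed_result()
        res.to_csv(tmp_path / "trials.csv")
        res.summary_json(tmp_path / "summary.json")
        assert (tmp_path / "trials.csv").exists()
        assert (tmp_path / "summary.json").exists()


class TestRunMotionTest:
    def test_scripted_source_completion_100(self):
        motions = ["a", "b", "c"]
        source = lambda mov, seed: scripted_stream(mov, [mov] * 30, CFG)
        res = run_motion_test(source, motions, CFG, rng_seed=0)
        # 3 motions x trials_per_motion 1 x n_tests 2
        assert res.n_attempted == 6
        assert res.completion_percentage == 100.0

    def test_deterministic_per_seed(self):
        motions = ["a", "b"]
        calls1, calls2 = [], []

        def make_source(log):
            def source(mov, seed):
                log.append((mov, seed))
                return scripted_stream(mov, [mov] * 30, CFG)
            return source

        run_motion_test(make_source(calls1), motions, CFG, rng_seed=5)
        run_motion_test(make_source(calls2), motions, CFG, rng_seed=5)
        assert calls1 == calls2

    def test_order_randomized_by_seed(self):
        motions = [f"m{i}" for i in range(8)]
        orders = {}
        for seed in (1, 2):
            calls = []
            run_motion_test(
                lambda mov, s, calls=calls: (calls.append(mov), scripted_stream(mov, [mov] * 30, CFG))[1],
                motions, CFG, rng_seed=seed,
            )
            orders[seed] = tuple(calls)
        assert orders[1] != orders[2]
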