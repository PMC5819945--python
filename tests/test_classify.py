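"""Classifier tests: alignment, activity labels, torpor bouts, winter metrics."""

import numpy as np
import pytest

from hiberphys import classify, simulate, trace
from hiberphys.classify import IN_NEST, OUTSIDE

from conftest import square_wave_traces
from naive_reference import naive_classify


class TestAlignAmbient:
    def test_constant_series_stays_constant(self):
        amb = trace.TemperatureTrace(np.arange(0, 301, 30.0), np.full(11, 20.0),
                                     source="ambient", sampling_interval=30)
        out = trace.align_ambient(amb, np.arange(0, 300.0))
        assert np.all(out.values == 20.0)

    def test_linear_interpolation_midpoint(self):
        amb = trace.TemperatureTrace([0.0, 30.0], [10.0, 13.0], source="ambient",
                                     sampling_interval=30)
        out = trace.align_ambient(amb, np.array([0.0, 10.0, 30.0]))
        assert out.values[1] == pytest.approx(11.0)

    def test_extrapolation_refused_with_span_in_message(self):
        amb = trace.TemperatureTrace([0.0, 30.0], [10.0, 13.0], source="ambient",
                                     sampling_interval=30)
        with pytest.raises(ValueError, match="span"):
            trace.align_ambient(amb, np.array([0.0, 45.0]))


class TestClassifyActivity:
    def test_identical_traces_all_in_nest(self, params):
        t = np.arange(0, 500.0)
        vals = np.full(t.size, 21.0)
        nest = trace.TemperatureTrace(t, vals, source="nest")
        amb = trace.TemperatureTrace(t, vals, source="ambient")
        with pytest.warns(UserWarning, match="constant"):
            seg = classify.classify_activity(nest, amb, params)
        assert seg.threshold == 0.0
        assert np.all(seg.labels == IN_NEST)
        assert seg.activity_time == 0.0

    def test_trace_shorter_than_window_rejected(self, params):
        t = np.arange(0, 50.0)
        nest = trace.TemperatureTrace(t, np.full(50, 25.0), source="nest")
        amb = trace.TemperatureTrace(t, np.full(50, 20.0), source="ambient")
        with pytest.raises(ValueError, match="ma_window"):
            classify.classify_activity(nest, amb, params)

    def test_square_wave_daily_activity_recovered(self, params):
        nest, amb, outside = square_wave_traces(days=3)
        seg = classify.classify_activity(nest, amb, params)
        per_day = seg.activity_time / 3
        assert per_day == pytest.approx(720.0, abs=params.ma_window)
        # label disagreement confined to transition slop around state changes
        mismatch = np.mean((seg.labels == OUTSIDE) != outside)
        assert mismatch < 0.02

    def test_square_wave_matches_naive_reference_exactly(self, params):
        nest, amb, _ = square_wave_traces(days=2)
        seg = classify.classify_activity(nest, amb, params)
        ref = naive_classify(nest.values, amb.values, params, 1.0)
        np.testing.assert_array_equal(seg.labels, ref)

    def test_generator_scenarios_match_naive_reference_exactly(self, params):
        for seed in range(5):
            cfg = simulate.ScenarioConfig(
                seed=seed, n_weeks=1,
                torpor_schedule=((3, 480.0, 240.0, 5.0),))
            nest, amb, _ = simulate.simulate_prehibernation_trace(cfg)
            aligned = trace.align_ambient(amb, nest.timestamps)
            cut = slice(0, 2000)
            nest_c = trace.TemperatureTrace(nest.timestamps[cut], nest.values[cut],
                                            source="nest")
            amb_c = trace.TemperatureTrace(aligned.timestamps[cut],
                                           aligned.values[cut], source="ambient")
            seg = classify.classify_activity(nest_c, amb_c, params)
            ref = naive_classify(nest_c.values, amb_c.values, params, 1.0)
            np.testing.assert_array_equal(seg.labels, ref, err_msg=f"seed {seed}")

    def test_midnight_nest_return_relabelled_in_nest(self, params):
        # a 30-min gap between the two nightly excursions is a nest return
        cfg = simulate.ScenarioConfig(
            seed=21, n_weeks=1,
            activity_episodes=((1080.0, 240.0), (1350.0, 450.0)))
        nest, amb, truth = simulate.simulate_prehibernation_trace(cfg)
        aligned = trace.align_ambient(amb, nest.timestamps)
        seg = classify.classify_activity(nest, aligned, params)
        gap = (nest.timestamps % 1440 >= 1320) & (nest.timestamps % 1440 < 1350)
        frac_in_nest = np.mean(seg.labels[gap] == IN_NEST)
        assert frac_in_nest > 0.7

    def test_weekly_activity_close_to_programmed_truth(self, params):
        cfg = simulate.ScenarioConfig(seed=22, n_weeks=2)
        nest, amb, truth = simulate.simulate_prehibernation_trace(cfg)
        aligned = trace.align_ambient(amb, nest.timestamps)
        seg = classify.classify_activity(nest, aligned, params)
        est = seg.activity_by_week(2)
        true = truth.activity_minutes_per_week(2, 1.0)
        np.testing.assert_allclose(est, true, rtol=0.05)

    def test_episodes_tile_the_trace(self, torpor_week, params):
        _, nest, aligned, _ = torpor_week
        seg = classify.classify_activity(nest, aligned, params)
        starts = [e[1] for e in seg.episodes]
        ends = [e[2] for e in seg.episodes]
        assert starts[0] == nest.timestamps[0]
        assert ends[-1] == nest.timestamps[-1] + nest.sampling_interval
        assert all(e == s for e, s in zip(ends[:-1], starts[1:]))
        total = sum(e - s for s, e in zip(starts, ends))
        in_nest = total - seg.activity_time
        assert in_nest + seg.activity_time == pytest.approx(total)


class TestDetectTorporBouts:
    def test_constant_euthermic_trace_has_no_bouts(self, params):
        t = np.arange(0, 1440.0)
        nest = trace.TemperatureTrace(t, np.full(t.size, 26.0), source="nest")
        amb = trace.TemperatureTrace(t, np.full(t.size, 20.0), source="ambient")
        with pytest.warns(UserWarning):
            seg = classify.classify_activity(nest, amb, params)
        assert classify.detect_torpor_bouts(nest, amb, seg, params) == []

    def test_daily_bouts_recovered_with_tight_boundaries(self, torpor_week, params):
        _, nest, aligned, truth = torpor_week
        seg = classify.classify_activity(nest, aligned, params)
        bouts = classify.detect_torpor_bouts(nest, aligned, seg, params)
        assert len(bouts) == len(truth.torpor_bouts) == 7
        for est, true in zip(bouts, truth.torpor_bouts):
            assert est.onset == pytest.approx(true.onset, abs=15)
            assert est.offset == pytest.approx(true.offset, abs=15)
            assert est.kind == "daily"

    def test_fast_cooling_is_not_torpor_slow_cooling_is(self, params):
        # same depth, contrasting kinetics: a nest exit versus a torpor entry
        fast = simulate.ScenarioConfig(seed=23, n_weeks=1,
                                       activity_episodes=((480.0, 180.0),))
        nest, amb, _ = simulate.simulate_prehibernation_trace(fast)
        aligned = trace.align_ambient(amb, nest.timestamps)
        seg = classify.classify_activity(nest, aligned, params)
        assert classify.detect_torpor_bouts(nest, aligned, seg, params) == []

        slow = simulate.ScenarioConfig(seed=23, n_weeks=1, activity_episodes=(),
                                       torpor_schedule=((0, 480.0, 300.0, 5.0),))
        nest2, amb2, _ = simulate.simulate_prehibernation_trace(slow)
        aligned2 = trace.align_ambient(amb2, nest2.timestamps)
        seg2 = classify.classify_activity(nest2, aligned2, params)
        assert len(classify.detect_torpor_bouts(nest2, aligned2, seg2, params)) == 1

    def test_min_duration_monotonicity(self, torpor_week, params):
        _, nest, aligned, _ = torpor_week
        seg = classify.classify_activity(nest, aligned, params)
        counts = []
        for min_dur in (30.0, 60.0, 120.0, 301.0, 600.0):
            p = classify.ClassifierParams(torpor_min_duration=min_dur)
            counts.append(len(classify.detect_torpor_bouts(nest, aligned, seg, p)))
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0


def _synthetic_seg(n_weeks=2, dt=1.0):
    n = int(n_weeks * 7 * 1440 / dt)
    t = np.arange(n) * dt
    labels = np.full(n, IN_NEST, dtype=np.int8)
    episodes = ((IN_NEST, 0.0, float(n * dt)),)
    return classify.ActivitySegmentation(timestamps=t, labels=labels,
                                         episodes=episodes, sampling_interval=dt,
                                         threshold=0.0)


class TestWeeklySummaries:
    def test_no_bouts_gives_zeros_with_activity(self):
        seg = _synthetic_seg(n_weeks=1)
        (week,) = classify.weekly_summaries([], seg, n_weeks=1)
        assert (week.torpor_frequency, week.total_torpor_duration,
                week.mean_torpor_duration) == (0, 0.0, 0.0)

    def test_two_bouts_frequency_total_mean(self):
        seg = _synthetic_seg(n_weeks=1)
        bouts = [classify.TorporBout(onset=100, offset=200, min_temp=20),
                 classify.TorporBout(onset=1000, offset=1200, min_temp=19)]
        (week,) = classify.weekly_summaries(bouts, seg, n_weeks=1)
        assert week.torpor_frequency == 2
        assert week.total_torpor_duration == 300.0
        assert week.mean_torpor_duration == 150.0

    def test_straddling_bout_counted_in_onset_week_full_duration(self):
        seg = _synthetic_seg(n_weeks=2)
        boundary = 7 * 1440.0
        bouts = [classify.TorporBout(onset=boundary - 100, offset=boundary + 200,
                                     min_temp=18)]
        w0, w1 = classify.weekly_summaries(bouts, seg, n_weeks=2)
        assert w0.torpor_frequency == 1 and w1.torpor_frequency == 0
        assert w0.total_torpor_duration == 300.0


class TestMergeRespirometryTorpor:
    def _weeks(self):
        return [classify.WeeklyTorporSummary(0, 2, 400.0, 200.0, 3000.0)]

    def test_no_missing_weeks_identity(self):
        weekly = self._weeks()
        assert classify.merge_respirometry_torpor(weekly, {0: False}) == weekly

    def test_true_flag_records_presence_without_durations(self):
        merged = classify.merge_respirometry_torpor(self._weeks(), {1: True})
        added = merged[1]
        assert added.torpor_frequency >= 1
        assert np.isnan(added.total_torpor_duration)
        assert np.isnan(added.activity_time)

    def test_false_flag_records_absence(self):
        merged = classify.merge_respirometry_torpor(self._weeks(), {1: False})
        added = merged[1]
        assert added.torpor_frequency == 0
        assert added.total_torpor_duration == 0.0
        assert np.isnan(added.activity_time)


def _square_bout_trace(bout_hours, euthermic=36.5, torpid=6.0, lead_min=600):
    segments = [np.full(lead_min, euthermic)]
    for h in bout_hours:
        segments.append(np.full(int(h * 60), torpid))
        segments.append(np.full(240, euthermic))
    vals = np.concatenate(segments)
    return trace.TemperatureTrace(np.arange(vals.size, dtype=float), vals,
                                  source="body")


class TestHibernationMetrics:
    def test_never_torpid_means_no_hibernation(self, params):
        body = _square_bout_trace([])
        pattern = classify.hibernation_metrics(body, params)
        assert not pattern.detected

    def test_23h_bout_is_below_the_24h_rule(self, params):
        pattern = classify.hibernation_metrics(_square_bout_trace([23.0]), params)
        assert not pattern.detected

    def test_25h_bout_starts_hibernation_at_its_onset(self, params):
        pattern = classify.hibernation_metrics(_square_bout_trace([25.0]), params)
        assert pattern.detected
        assert pattern.onset_time == 600.0
        assert pattern.arousal_frequency == 0

    def test_boundary_is_closed_at_exactly_24h(self, params):
        pattern = classify.hibernation_metrics(_square_bout_trace([24.0]), params)
        assert pattern.detected

    def test_three_bout_arithmetic(self, params):
        pattern = classify.hibernation_metrics(
            _square_bout_trace([30.0, 50.0, 80.0]), params)
        assert pattern.arousal_frequency == 2
        assert pattern.mean_ibe_duration == pytest.approx(4.0)
        assert pattern.mean_torpor_bout_duration == pytest.approx(160.0 / 3)
        assert pattern.min_tb <= params.euthermy_threshold_body

    def test_generator_scenario_close_to_truth(self, params):
        cfg = simulate.ScenarioConfig(seed=24, tau_hib_entry=5.0,
                                      tau_hib_arousal=5.0)
        body, truth = simulate.simulate_hibernation_trace(cfg)
        pattern = classify.hibernation_metrics(body, params)
        assert pattern.detected
        assert pattern.arousal_frequency == 2
        assert pattern.mean_ibe_duration == pytest.approx(4.0, abs=0.25)
        assert pattern.mean_torpor_bout_duration == pytest.approx(160.0 / 3,
                                                                  abs=0.5)
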