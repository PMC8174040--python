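import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from seqhorizon import (
    ForceTrace, GenerativeParams, PressEvent, ThresholdState, TrialRecord,
    award_points, compute_ipis, compute_mt, compute_rt, detect_presses,
    sample_sequence, simulate_trial, synthesize_force_trace, trial_summary,
    update_threshold,
)
from seqhorizon.events import ipi_frame


def _pulse_trace(tp=100.0, tr=250.0, key=1, dt=5.0, peak=2.0, t_end=400.0):
    t = np.arange(0.0, t_end, dt)
    f = np.zeros((t.size, 5))
    inside = (t >= tp) & (t <= tr)
    f[inside, key - 1] = peak
    return ForceTrace(times=t, forces=f)


class TestDetectPresses:
    def test_single_pulse(self):
        events = detect_presses(_pulse_trace(tp=100, tr=250))
        assert len(events) == 1
        assert events[0].key == 1
        assert events[0].press_time == 100.0
        assert events[0].release_time == 255.0  # first sample back below

    def test_subthreshold_force_yields_no_events(self):
        t = np.arange(0, 500, 5.0)
        f = np.full((t.size, 5), 0.5)
        assert detect_presses(ForceTrace(times=t, forces=f)) == []

    def test_trace_ending_mid_press_has_missing_release(self):
        events = detect_presses(_pulse_trace(tp=100, tr=1000, t_end=400))
        assert len(events) == 1
        assert math.isnan(events[0].release_time)

    def test_short_dip_is_debounced(self):
        t = np.arange(0, 400, 5.0)
        f = np.zeros((t.size, 5))
        f[(t >= 100) & (t <= 200), 0] = 2.0
        f[(t > 210) & (t <= 300), 0] = 2.0  # 10 ms dip < 20 ms debounce
        events = detect_presses(ForceTrace(times=t, forces=f))
        assert len(events) == 1
        f2 = f.copy()
        f2[(t > 210) & (t <= 240), 0] = 0.0  # 35 ms gap: two presses
        events2 = detect_presses(ForceTrace(times=t, forces=f2))
        assert len(events2) == 2

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_presses(ForceTrace(times=np.array([]),
                                      forces=np.zeros((0, 5))))

    @pytest.mark.parametrize("w", [1, 3, 8, 14])
    def test_roundtrip_recovers_scheduled_presses(self, noiseless_params, w):
        """Detection on noiseless synthesized traces reproduces the
        scheduled press/release times within one sampling interval."""
        p = noiseless_params
        rng = np.random.default_rng(w)
        seq = sample_sequence(p.n_digits, p.seq_length, rng)
        trial = simulate_trial(p, w, seq, 1, rng)
        trace = synthesize_force_trace(trial, p)
        events = detect_presses(trace)
        assert len(events) == p.seq_length
        dt = 1000.0 / p.sample_rate_hz
        for det, sched in zip(events, trial.events):
            assert det.key == sched.key
            assert abs(det.press_time - sched.press_time) <= dt
            assert abs(det.release_time - sched.release_time) <= dt


def _toy_trial(press_times, stim=0.0, durs=100.0):
    events = [PressEvent(key=1 + i % 5, press_time=t, release_time=t + durs)
              for i, t in enumerate(press_times)]
    return TrialRecord(participant=1, day=1, block=1, trial=1, w=5,
                       stim_onset=stim,
                       target=tuple(e.key for e in events), events=events)


class TestTimingDefinitions:
    def test_rt_is_first_press_minus_onset(self):
        trial = _toy_trial([750.0 + 500 * i for i in range(14)])
        assert compute_rt(trial) == 750.0
        # invariant to everything after the first press
        trial2 = _toy_trial([750.0] + [2000.0 + 100 * i for i in range(13)])
        assert compute_rt(trial2) == 750.0

    def test_mt_first_press_to_last_release(self):
        trial = _toy_trial([1000.0 + 250 * i for i in range(14)], durs=250.0)
        assert compute_mt(trial) == (1000 + 13 * 250 + 250) - 1000

    def test_equal_spacing_gives_constant_ipis(self):
        trial = _toy_trial([500.0 * i for i in range(14)])
        assert np.allclose(compute_ipis(trial), 500.0)

    def test_telescoping_identities(self, cohort):
        """Sum of IPIs equals press14 - press1, and MT equals that plus the
        final press duration, on every simulated trial."""
        for trial in cohort.records[::97]:
            ipis = compute_ipis(trial)
            onsets = [e.press_time for e in trial.events]
            assert ipis.sum() == pytest.approx(onsets[-1] - onsets[0])
            last_dur = trial.events[-1].release_time - onsets[-1]
            assert compute_mt(trial) == pytest.approx(ipis.sum() + last_dur)

    def test_missing_events_handled(self):
        short = _toy_trial([100.0, 600.0])
        trial = TrialRecord(participant=1, day=1, block=1, trial=1, w=5,
                            stim_onset=0.0, target=tuple([1] * 14),
                            events=short.events)
        assert trial.is_error
        assert math.isnan(compute_mt(trial))
        with pytest.raises(ValueError):
            compute_ipis(trial)


class TestRewardRules:
    def test_threshold_drops_5pct_when_criteria_met(self):
        s = ThresholdState(current_threshold=4000, best_median_mt=3200)
        out = update_threshold(s, block_median_mt=3000, block_error_rate=0.10)
        assert out.current_threshold == pytest.approx(3800)
        assert out.best_median_mt == 3000

    def test_threshold_unchanged_on_high_error_rate(self):
        s = ThresholdState(current_threshold=4000, best_median_mt=3200)
        assert update_threshold(s, 3000, 0.20) is s

    def test_threshold_requires_strictly_faster_median(self):
        s = ThresholdState(current_threshold=4000, best_median_mt=3200)
        assert update_threshold(s, 3200, 0.10) is s

    @pytest.mark.parametrize("is_error,mt,expected", [
        (True, 2000.0, 0),
        (False, 0.95 * 4000.0, 3),   # exactly 5% faster counts
        (False, 4000.0, 1),
        (False, 3900.0, 1),
    ])
    def test_points(self, is_error, mt, expected):
        assert award_points(is_error, mt, threshold=4000.0) == expected

    @given(medians=hst.lists(hst.floats(1000, 8000), min_size=1, max_size=30),
           errors=hst.lists(hst.floats(0, 1), min_size=30, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_threshold_sequence_non_increasing(self, medians, errors):
        state = ThresholdState(current_threshold=5000.0)
        thresholds = [state.current_threshold]
        for med, err in zip(medians, errors):
            state = update_threshold(state, med, err)
            thresholds.append(state.current_threshold)
        assert all(b <= a for a, b in zip(thresholds, thresholds[1:]))


class TestSummaries:
    def test_error_flagged_and_excluded_from_ipis(self, cohort, summary):
        frame = cohort.frame
        wrong = frame[frame["produced_digit"] != frame["target_digit"]]
        some = wrong.iloc[0]
        row = summary[(summary["participant"] == some["participant"])
                      & (summary["day"] == some["day"])
                      & (summary["block"] == some["block"])
                      & (summary["trial"] == some["trial"])]
        assert bool(row["is_error"].iloc[0])
        ipis = ipi_frame(frame)
        merged = ipis.merge(summary[summary["is_error"]],
                            on=["participant", "day", "block", "trial"],
                            how="inner")
        assert merged.empty
        good = summary[~summary["is_error"]]
        assert len(ipis) == 13 * len(good)

    def test_block_summary_threshold_monotone(self, summary):
        from seqhorizon import block_summary

        blocks = block_summary(summary)
        for _, g in blocks.groupby("participant"):
            thr = g.sort_values(["day", "block"])["threshold_ms"].to_numpy()
            assert (np.diff(thr) <= 1e-9).all()
        assert blocks["points"].between(0, 3 * 18).all()
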