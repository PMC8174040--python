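import collections

import numpy as np
import pandas as pd
import pytest

from seqhorizon import (
    GenerativeParams, compute_ipis, compute_mt, sample_sequence,
    scheduled_profile, simulate_experiment, simulate_trial, trial_summary,
)


class TestSampleSequence:
    def test_shuffle_concatenation_counts(self, rng):
        seq = sample_sequence(5, 14, rng)
        assert len(seq) == 14
        counts = collections.Counter(seq)
        assert set(counts) <= {1, 2, 3, 4, 5}
        assert all(c in (2, 3) for c in counts.values())

    def test_single_shuffle_is_permutation(self, rng):
        assert sorted(sample_sequence(5, 5, rng)) == [1, 2, 3, 4, 5]

    def test_deterministic_under_seeding(self):
        a = sample_sequence(5, 14, np.random.default_rng(7))
        b = sample_sequence(5, 14, np.random.default_rng(7))
        assert a == b

    @pytest.mark.parametrize("n_digits,seq_length", [(5, 0), (5, -3), (1, 14)])
    def test_invalid_arguments(self, n_digits, seq_length, rng):
        with pytest.raises(ValueError):
            sample_sequence(n_digits, seq_length, rng)


class TestSimulateTrial:
    def _trial(self, params, w, day=1, seed=0):
        rng = np.random.default_rng(seed)
        seq = sample_sequence(params.n_digits, params.seq_length, rng)
        return simulate_trial(params, w, seq, day, rng)

    def test_w1_profile_flat_without_noise(self, noiseless_params):
        ipis = compute_ipis(self._trial(noiseless_params, 1))
        assert np.allclose(ipis, ipis[0])
        assert ipis[0] == pytest.approx(noiseless_params.sr_time)

    def test_full_view_faster_than_serial(self, noiseless_params):
        mt1 = compute_mt(self._trial(noiseless_params, 1))
        mt14 = compute_mt(self._trial(noiseless_params, 14))
        assert mt14 < mt1

    def test_mt_matches_scheduled_ipis(self, noiseless_params):
        """Noise-free MT equals the generator's own schedule: sum of the 13
        scheduled IPIs plus the final press duration."""
        for w in (1, 3, 8, 14):
            trial = self._trial(noiseless_params, w)
            _, ipis, durs = scheduled_profile(noiseless_params, w, 1)
            assert compute_mt(trial) == pytest.approx(ipis.sum() + durs[-1])
            assert compute_ipis(trial) == pytest.approx(ipis)

    def test_rejects_unknown_window(self, noiseless_params, rng):
        seq = sample_sequence(5, 14, rng)
        with pytest.raises(ValueError):
            simulate_trial(noiseless_params, 9, seq, 1, rng)

    def test_first_last_discount_speeds_edge_transitions(self):
        p = GenerativeParams(noise_cv=0.0, press_error_rate=0.0)
        ipis = compute_ipis(self._trial(p, 14))
        assert ipis[0] < ipis[5]
        assert ipis[-1] < ipis[5]
        # w=1 remains flat: the speed-up only applies when w >= 2
        flat = compute_ipis(self._trial(p, 1))
        assert np.allclose(flat, flat[0])


class TestSimulateExperiment:
    def test_minimal_design_trial_count(self):
        p = GenerativeParams(n_participants=1, n_days=1, blocks_per_day=1,
                             seed=2)
        exp = simulate_experiment(p)
        assert len(exp.records) == 27

    def test_design_is_full_factorial(self, cohort, cohort_params):
        p = cohort_params
        assert len(cohort.records) == (p.n_participants * p.n_days
                                       * p.blocks_per_day * p.trials_per_block)
        counts = cohort.frame.groupby(["participant", "day", "block"])["trial"].nunique()
        assert (counts == p.trials_per_block).all()

    def test_windows_balanced_within_block(self, cohort, cohort_params):
        per_block = (cohort.frame.drop_duplicates(
            ["participant", "day", "block", "trial"])
            .groupby(["participant", "day", "block"])["w"]
            .value_counts().unstack())
        reps = cohort_params.trials_per_block // len(cohort_params.window_set)
        assert (per_block == reps).all().all()

    def test_truth_records_horizon_per_participant_day(self, cohort, cohort_params):
        p = cohort_params
        assert len(cohort.truth) == p.n_participants * p.n_days
        assert (cohort.truth["w_star_true"] > 1).all()
        # horizon expands with practice for every participant
        g = cohort.truth.groupby("participant")["w_star_true"]
        assert (g.apply(lambda s: s.is_monotonic_increasing)).all()

    def test_bit_identical_under_same_seed(self):
        p = GenerativeParams(n_participants=2, n_days=1, blocks_per_day=2,
                             trials_per_block=9, seed=42)
        f1 = simulate_experiment(p).frame
        f2 = simulate_experiment(p).frame
        pd.testing.assert_frame_equal(f1, f2)

    def test_adding_participants_preserves_existing_data(self):
        base = dict(n_days=1, blocks_per_day=2, trials_per_block=9, seed=9)
        small = simulate_experiment(GenerativeParams(n_participants=2, **base))
        large = simulate_experiment(GenerativeParams(n_participants=4, **base))
        sub = large.frame[large.frame["participant"] <= 2].reset_index(drop=True)
        pd.testing.assert_frame_equal(small.frame, sub)

    def test_trial_error_rate_matches_closed_form(self, summary, cohort_params):
        """P(error trial) -> 1 - (1 - p)^14; check within binomial CI and
        that the calibrated default lands in the study's 10-15% band."""
        p = cohort_params.press_error_rate
        expected = 1.0 - (1.0 - p) ** cohort_params.seq_length
        assert 0.10 <= expected <= 0.15
        n = len(summary)
        observed = summary["is_error"].mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * se

    def test_group_rt_calibration_for_large_windows(self, summary):
        ok = summary[~summary["is_error"]]
        rt_large = ok[ok["w"] >= 4].groupby("participant")["rt_ms"].mean().mean()
        assert 700 <= rt_large <= 800


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(n_participants=0), dict(w_star_true=1.0),
        dict(press_error_rate=1.0), dict(window_set=(0, 3)),
        dict(window_set=(1, 20)), dict(sr_time=100.0),  # slower than asymptote
        dict(noise_cv=-0.1),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            GenerativeParams(**bad)

    def test_roundtrip_json(self, tmp_path):
        p = GenerativeParams(seed=7, w_star_true=3.5)
        p.to_json(tmp_path / "p.json")
        assert GenerativeParams.from_json(tmp_path / "p.json") == p
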