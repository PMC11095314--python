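import numpy as np
import pytest

import phyloemg as pe
from phyloemg.detection import _runs_at_thresholds
from phyloemg.errors import DegenerateSignalError, ValidationError


from oracles import brute_force_scan


class TestCountRuns:
    @pytest.mark.parametrize(
        "env,thr,expected",
        [
            ([0, 1, 1, 0, 2, 0, 1], 0.5, 3),
            ([0, 1, 1, 0, 2, 0, 1], 2.0, 0),  # thr >= max
            ([3, 3, 3], 1.0, 1),  # all supra-threshold
            ([], 0.0, 0),
        ],
    )
    def test_examples(self, env, thr, expected):
        assert pe.count_runs(np.array(env, dtype=float), thr) == expected

    def test_extreme_thresholds(self):
        rng = np.random.default_rng(0)
        env = rng.uniform(1.0, 2.0, 300)
        assert pe.count_runs(env, env.min() - 1e-9) == 1
        assert pe.count_runs(env, env.max()) == 0

    def test_vectorized_counts_match_scalar(self):
        rng = np.random.default_rng(4)
        env = rng.uniform(0.0, 1.0, 500)
        thresholds = np.sort(rng.uniform(0.0, 1.0, 50))
        vec = _runs_at_thresholds(env, thresholds)
        scalar = [pe.count_runs(env, th) for th in thresholds]
        np.testing.assert_array_equal(vec, scalar)


class TestRandomizationThreshold:
    def test_two_level_envelope(self, square_envelope):
        env, _ = square_envelope
        scan = pe.randomization_threshold(env, seed=1)
        assert 0.1 < scan.optimal_threshold < 1.0
        assert scan.optimal_threshold in scan.thresholds

    def test_thresholds_span_range_in_equal_steps(self, square_envelope):
        env, _ = square_envelope
        scan = pe.randomization_threshold(env, seed=0)
        assert scan.thresholds.size == 50
        steps = np.diff(scan.thresholds)
        np.testing.assert_allclose(steps, np.ptp(env) / 50, rtol=1e-9)
        assert scan.thresholds[-1] == pytest.approx(env.max())

    def test_constant_envelope_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pe.randomization_threshold(np.full(200, 3.0), seed=0)

    def test_detection_stable_across_permutation_counts(self):
        # at SNR 10 a single shuffle and a 20-shuffle average land on the
        # diff plateau within a couple of grid steps of each other, and the
        # bursts they yield agree to within 20 ms
        strides = pe.gen_stride_events(9, stance_s=0.5, swing_s=0.2, seed=0, start_s=0.5)
        sched = pe.stride_burst_schedule(
            "ch", strides, 0.0, 0.6, gain=50.0, background_rms=5.0
        )
        rec, _ = pe.gen_emg_recording(
            sched, 5000.0, float(strides.touchdowns[-1] + 0.5), seed=1
        )
        pc = pe.process_emg(rec)["ch"]
        results = []
        for n_perm in (1, 20):
            cfg = pe.RunConfig(seed=5, n_permutations=n_perm)
            bursts, scan = pe.detect_channel(pc, cfg)
            results.append((bursts, scan))
        (b1, s1), (b20, s20) = results
        grid = np.diff(s1.thresholds)[0]
        assert abs(s1.optimal_threshold - s20.optimal_threshold) <= 3 * grid
        assert len(b1) == len(b20)
        for x, y in zip(b1, b20):
            assert x.onset_s == pytest.approx(y.onset_s, abs=0.02)
            assert x.offset_s == pytest.approx(y.offset_s, abs=0.02)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            base = rng.uniform(0.5, 1.0)
            env = base + rng.uniform(0, 0.2, 400)
            a, b = sorted(rng.integers(50, 350, 2))
            env[a : max(b, a + 20)] += rng.uniform(2.0, 5.0)
            fast = pe.randomization_threshold(env, seed=trial).optimal_threshold
            assert fast == pytest.approx(brute_force_scan(env, seed=trial), abs=1e-12)

    def test_shift_invariance(self, square_envelope):
        env, _ = square_envelope
        scan = pe.randomization_threshold(env, seed=3)
        shifted = pe.randomization_threshold(env + 10.0, seed=3)
        assert shifted.optimal_threshold == pytest.approx(scan.optimal_threshold + 10.0)


class TestDetectBursts:
    def test_square_envelope_single_interval(self, square_envelope):
        env, fs = square_envelope
        ivs = pe.detect_bursts(env, fs, 0.5)
        assert len(ivs) == 1
        a, b = ivs[0]
        assert a == pytest.approx(500 / fs, abs=1.0 / fs)
        assert b == pytest.approx(1000 / fs, abs=1.0 / fs)

    def test_threshold_above_max_empty(self, square_envelope):
        env, fs = square_envelope
        assert pe.detect_bursts(env, fs, 2.0) == []

    def test_offset_is_exclusive_sample_time(self):
        env = np.array([0.0, 1.0, 1.0, 0.0])
        ivs = pe.detect_bursts(env, 500.0, 0.5)
        assert ivs == [(1 / 500.0, 3 / 500.0)]


class TestMergeAndFilter:
    def test_short_gap_merged_long_gap_kept(self):
        ivs = [(0.0, 0.1), (0.105, 0.2), (0.4, 0.5)]
        out = pe.merge_and_filter(ivs, max_merge_gap=0.02, min_duration=0.03)
        assert out == [(0.0, 0.2), (0.4, 0.5)]

    def test_all_too_short_dropped(self):
        ivs = [(0.0, 0.01), (0.5, 0.52)]
        assert pe.merge_and_filter(ivs, max_merge_gap=0.0, min_duration=0.03) == []

    def test_zero_gap_identity_on_disjoint(self):
        ivs = [(0.0, 0.1), (0.2, 0.3)]
        assert pe.merge_and_filter(ivs, max_merge_gap=0.0, min_duration=0.0) == ivs


class TestMeanAmplitude:
    def test_constant_signal(self):
        x = np.full(500, 5.0)
        assert pe.mean_amplitude(x, 500.0, (0.1, 0.9)) == pytest.approx(5.0)

    def test_linear_ramp(self):
        fs = 500.0
        x = np.linspace(0.0, 10.0, 501)
        assert pe.mean_amplitude(x, fs, (0.0, 1.0)) == pytest.approx(5.0, rel=1e-6)

    def test_half_sine(self):
        fs = 500.0
        t = np.arange(0, 1.0, 1 / fs)
        A = 7.0
        x = A * np.sin(np.pi * t)
        assert pe.mean_amplitude(x, fs, (0.0, 1.0 - 1 / fs)) == pytest.approx(
            2 * A / np.pi, rel=0.01
        )

    def test_interval_outside_support_rejected(self):
        with pytest.raises(ValidationError):
            pe.mean_amplitude(np.ones(100), 500.0, (0.1, 5.0))


class TestSelectPrimaryBurst:
    def make(self, onset, dur, amp):
        return pe.BurstInterval("ch", onset, onset + dur, mean_amplitude=amp)

    def test_higher_amplitude_wins(self):
        bursts = [self.make(0.0, 0.2, 10.0), self.make(0.5, 0.4, 3.0)]
        assert pe.select_primary_burst(bursts).mean_amplitude == 10.0

    def test_single_burst_returned(self):
        b = self.make(0.1, 0.2, 4.0)
        assert pe.select_primary_burst([b]) is b

    def test_duration_breaks_amplitude_tie(self):
        bursts = [self.make(0.0, 0.1, 5.0), self.make(0.5, 0.3, 5.0)]
        assert pe.select_primary_burst(bursts).duration_s == pytest.approx(0.3)

    def test_earlier_onset_breaks_full_tie(self):
        bursts = [self.make(0.5, 0.2, 5.0), self.make(0.0, 0.2, 5.0)]
        assert pe.select_primary_burst(bursts).onset_s == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pe.select_primary_burst([])


class TestFullChain:
    def test_recovers_snr5_bursts(self, snr5_processed):
        # every true burst is matched within 20 ms on both edges; the
        # randomization threshold sits near the noise ceiling, so a few
        # spurious short noise excursions may also be reported
        pc, truth, _ = snr5_processed
        bursts, scan = pe.detect_channel(pc, pe.RunConfig(seed=1))
        true_ivs = truth.burst_intervals["PEC_sim_ch1"]
        for a_true, b_true in true_ivs:
            matches = [
                b
                for b in bursts
                if abs(b.onset_s - a_true) <= 0.02 and abs(b.offset_s - b_true) <= 0.02
            ]
            assert len(matches) == 1, f"true burst ({a_true}, {b_true}) not recovered"
            assert matches[0].mean_amplitude > 0
        assert len(bursts) - len(true_ivs) <= 3
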