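"""Rhythm-index tests: intervals, index panel, long-beat flags, Poincaré,
morphology classification, and stochastic parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfecg import (
    Beat,
    BeatSet,
    IntervalSeries,
    RhythmAnalysis,
    SimConfig,
    classify_ecg,
    compute_indices,
    flag_long_beats,
    poincare_pairs,
    pp_intervals,
    simulate_recording,
)
from zfecg.errors import InsufficientBeatsError, InsufficientDataError
from zfecg.synth import base_interval_moments


def beats_from_times(times, p_amp=0.045):
    return BeatSet(
        beats=[Beat(p_time_s=t, p_amp_mV=p_amp) for t in times],
        trace_duration_s=float(times[-1]) + 1.0,
    )


class TestIntervals:
    def test_successive_differences(self):
        iv = pp_intervals(beats_from_times([0.0, 0.5, 1.0]))
        assert np.allclose(iv.pp_s, [0.5, 0.5])
        assert iv.recording_duration_min == pytest.approx(1.0 / 60.0)

    def test_n_minus_one_intervals(self):
        times = np.cumsum([0.522] * 116)
        assert len(pp_intervals(beats_from_times(times))) == 115

    def test_single_beat_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            pp_intervals(beats_from_times([1.0]))

    def test_detected_intervals_match_truth_noiselessly(self, wt_noiseless):
        trace, truth = wt_noiseless
        res = RhythmAnalysis(trace).fit()
        assert res.n_beats == truth.p_times_s.size
        assert np.max(np.abs(res.intervals.pp_s - truth.intervals_s)) <= 1.0 / trace.fs


class TestIndices:
    def test_heart_rate_is_sixty_over_mean_pp(self):
        times = np.arange(20) * 0.52
        beats = beats_from_times(times)
        iv = pp_intervals(beats)
        ix = compute_indices(beats, iv)
        assert ix.hr_bpm == pytest.approx(60.0 / 0.52)
        # definitional identity, exact to float precision
        assert ix.hr_bpm * ix.mean_pp_s == pytest.approx(60.0, abs=1e-12)

    def test_p_over_r_ratio(self):
        beats = BeatSet(
            beats=[Beat(p_time_s=t, p_amp_mV=0.045, qrs_onset_s=t + 0.033,
                        r_time_s=t + 0.06, r_amp_mV=0.248,
                        qrs_offset_s=t + 0.085, qrs_detected=True)
                   for t in np.arange(10) * 0.52],
            trace_duration_s=6.0,
        )
        ix = compute_indices(beats, pp_intervals(beats))
        assert ix.p_over_r_ratio == pytest.approx(0.045 / 0.248)
        assert ix.p_over_r_ratio == pytest.approx(0.181, abs=0.001)
        assert ix.mean_pr_s == pytest.approx(0.033)
        assert ix.mean_qrs_s == pytest.approx(0.052)

    def test_constant_intervals_have_zero_sd(self):
        beats = beats_from_times(np.arange(10) * 0.5)
        ix = compute_indices(beats, pp_intervals(beats))
        assert ix.sd_pp_s == 0.0

    def test_no_qrs_leaves_fields_absent_not_zero(self):
        beats = beats_from_times(np.arange(10) * 0.5)
        ix = compute_indices(beats, pp_intervals(beats))
        assert ix.mean_r_amp_mV is None
        assert ix.mean_pr_s is None
        assert ix.mean_qrs_s is None
        assert ix.p_over_r_ratio is None

    @given(st.lists(st.floats(0.3, 2.0), min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sd_matches_two_pass_formula(self, pp):
        iv = IntervalSeries(pp_s=np.array(pp), recording_duration_min=1.0)
        beats = beats_from_times(np.concatenate([[0.0], np.cumsum(pp)]))
        ix = compute_indices(beats, iv)
        m = sum(pp) / len(pp)
        two_pass = (sum((x - m) ** 2 for x in pp) / (len(pp) - 1)) ** 0.5
        assert ix.sd_pp_s == pytest.approx(two_pass, abs=1e-12)


class TestLongBeatFlags:
    def test_constant_series_has_no_flags(self):
        iv = IntervalSeries(np.full(20, 0.52), 0.2)
        assert flag_long_beats(iv).size == 0

    def test_single_outlier_flagged(self):
        pp = np.array([0.5] * 19 + [1.4])
        flags = flag_long_beats(IntervalSeries(pp, 0.2))
        # mean=0.545, sd=0.2012 -> threshold 0.948: only index 19 exceeds
        assert flags.tolist() == [19]

    def test_flags_invariant_under_time_reversal(self):
        rng = np.random.default_rng(3)
        pp = rng.normal(0.52, 0.1, size=50).clip(0.3)
        pp[[7, 33]] = 1.5
        f_fwd = set(flag_long_beats(IntervalSeries(pp, 0.4)).tolist())
        f_rev = set(flag_long_beats(IntervalSeries(pp[::-1].copy(), 0.4)).tolist())
        assert {len(pp) - 1 - i for i in f_rev} == f_fwd

    def test_requires_three_intervals(self):
        with pytest.raises(InsufficientDataError):
            flag_long_beats(IntervalSeries(np.array([0.5, 0.6]), 0.02))


class TestPoincare:
    def test_constant_rhythm_sits_on_identity_line(self):
        iv = IntervalSeries(np.full(30, 0.52), 0.25)
        pc = poincare_pairs(iv)
        assert pc.pairs.shape == (29, 2)
        assert np.allclose(pc.pairs[:, 0], pc.pairs[:, 1])
        assert pc.sd1 == pytest.approx(0.0, abs=1e-12)
        assert pc.sd2 == pytest.approx(0.0, abs=1e-12)

    def test_pair_count_is_intervals_minus_one(self):
        rng = np.random.default_rng(0)
        pp = rng.uniform(0.4, 0.7, size=41)
        assert poincare_pairs(IntervalSeries(pp, 0.4)).pairs.shape[0] == 40

    def test_insufficient_intervals_rejected(self):
        with pytest.raises(InsufficientDataError):
            poincare_pairs(IntervalSeries(np.array([0.5]), 0.01))

    def test_mutant_cloud_contains_long_pause_ordinates(self):
        cfg = SimConfig.class_ii(seed=21)
        trace, _ = simulate_recording(cfg)
        res = RhythmAnalysis(trace).fit()
        pc = res.poincare
        assert pc.pairs.max() > 1.3
        # wild-type cloud stays tight around the identity line
        cfg_wt = SimConfig.wildtype(seed=21)
        res_wt = RhythmAnalysis(simulate_recording(cfg_wt)[0]).fit()
        assert res_wt.poincare.pairs.max() < 1.3
        assert res_wt.poincare.sd1 < pc.sd1


class TestClassification:
    def test_obvious_class_i(self):
        ix = compute_indices_stub(qrs_detectability=1.0, mean_r=0.5)
        assert classify_ecg(ix, noise_floor_mV=0.005) == "I"

    def test_low_detectability_is_class_ii(self):
        ix = compute_indices_stub(qrs_detectability=0.3, mean_r=0.5)
        assert classify_ecg(ix, noise_floor_mV=0.005) == "II"

    def test_amplitude_below_noise_is_class_ii(self):
        ix = compute_indices_stub(qrs_detectability=0.9, mean_r=0.012)
        assert classify_ecg(ix, noise_floor_mV=0.005) == "II"

    def test_labeled_cohorts_classified_perfectly(self):
        # every default-parameter synthetic recording must land in its
        # generating class
        for seed in range(4):
            for maker, label in [(SimConfig.wildtype, "I"),
                                 (SimConfig.class_i, "I"),
                                 (SimConfig.class_ii, "II")]:
                trace, truth = simulate_recording(maker(seed=50 + seed))
                res = RhythmAnalysis(trace).fit()
                assert res.indices.ecg_class == label, (maker.__name__, seed)


def compute_indices_stub(qrs_detectability, mean_r):
    from zfecg.metrics import ECGIndices

    return ECGIndices(
        hr_bpm=115.0, mean_pp_s=0.52, sd_pp_s=0.07, mean_p_amp_mV=0.045,
        mean_r_amp_mV=mean_r, p_over_r_ratio=None, mean_pr_s=0.033,
        mean_qrs_s=0.05, qrs_detectability=qrs_detectability,
    )


class TestParameterRecovery:
    @pytest.mark.parametrize("mean_pp,sd_pp", [(0.52, 0.074), (0.54, 0.135)])
    def test_mean_and_sd_recovered_within_three_se(self, mean_pp, sd_pp):
        """Detected P-P statistics over 50 replicate recordings recover the
        generating truncated-normal moments within 3 SE."""
        cfg0 = SimConfig.wildtype(mean_pp_s=mean_pp, sd_pp_s=sd_pp,
                                  duration_s=30.0)
        true_mean, true_sd = base_interval_moments(cfg0)
        pooled = []
        for s in range(50):
            trace, _ = simulate_recording(cfg0.replace(seed=300 + s))
            res = RhythmAnalysis(trace).fit()
            pooled.append(res.intervals.pp_s)
        pooled = np.concatenate(pooled)
        n = pooled.size
        se_mean = true_sd / np.sqrt(n)
        se_sd = true_sd / np.sqrt(2 * n)
        assert abs(pooled.mean() - true_mean) <= 3 * se_mean
        assert abs(pooled.std(ddof=1) - true_sd) <= 3 * se_sd
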