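"""Generator tests: rhythm schedule, waveform rendering, cohorts, genotyping."""

import numpy as np
import pytest
from scipy import signal

from zfecg import (
    AlleleModel,
    SimConfig,
    generate_beat_schedule,
    genotype_fragments,
    render_trace,
    simulate_cohort,
    simulate_recording,
)
from zfecg.errors import ConfigError


class TestSchedule:
    def test_deterministic_given_seed(self):
        cfg = SimConfig.class_ii(seed=42)
        a = generate_beat_schedule(cfg)
        b = generate_beat_schedule(cfg)
        assert np.array_equal(a.p_times_s, b.p_times_s)
        assert a.injected_pause_indices == b.injected_pause_indices

    def test_no_injection_when_rate_zero(self):
        cfg = SimConfig.wildtype(seed=1)
        truth = generate_beat_schedule(cfg)
        assert truth.injected_pause_indices == []
        assert truth.intervals_s.max() < cfg.mean_pp_s + 5 * cfg.sd_pp_s

    def test_wildtype_beat_count_near_115(self):
        # 60 s at a 0.52 s mean cycle -> ~115 beats (the ~115 bpm rate)
        counts = [
            generate_beat_schedule(SimConfig.wildtype(seed=s)).p_times_s.size
            for s in range(10)
        ]
        assert 110 <= np.mean(counts) <= 118

    def test_beat_count_consistency_monte_carlo(self):
        # with no SA the expected count is duration/mean_pp within 3 SD
        cfg = SimConfig.wildtype()
        counts = np.array([
            generate_beat_schedule(cfg.replace(seed=s)).p_times_s.size
            for s in range(200)
        ])
        expected = cfg.duration_s / cfg.mean_pp_s
        assert abs(counts.mean() - expected) <= 3 * counts.std(ddof=1)

    def test_injection_rate_monte_carlo(self):
        # Poisson injection model: mean surviving episodes/min within 3 SE
        # of the nominal rate over many replicate schedules
        cfg = SimConfig.class_ii(sa_rate_per_min=1.6, p_consecutive=0.0)
        per_min = []
        for s in range(1000):
            t = generate_beat_schedule(cfg.replace(seed=s))
            span_min = (t.p_times_s[-1] - t.p_times_s[0]) / 60.0
            per_min.append(len(t.injected_pause_indices) / span_min)
        per_min = np.array(per_min)
        se = per_min.std(ddof=1) / np.sqrt(per_min.size)
        assert abs(per_min.mean() - 1.6) <= 3 * se

    def test_injected_pauses_exceed_cutoff_and_base_never_does(self):
        cfg = SimConfig.class_ii(seed=9, p_consecutive=0.5)
        truth = generate_beat_schedule(cfg)
        iv = truth.intervals_s
        inj = np.asarray(truth.injected_pause_indices, dtype=int)
        assert np.all(iv[inj] > cfg.sa_pause_min_s)
        base = np.delete(iv, inj)
        assert np.all(base < 1.3)  # mean + 6 sd = 1.14 < cutoff

    def test_rejects_overfull_pause_schedule(self):
        with pytest.raises(ConfigError):
            SimConfig(sa_rate_per_min=40.0, sa_pause_min_s=2.0,
                      sa_pause_max_s=3.0, duration_s=60.0)

    @pytest.mark.parametrize("field,value", [
        ("duration_s", -1.0),
        ("fs", 50.0),
        ("sd_pp_s", 0.0),
        ("sd_pp_s", 0.6),
        ("sa_pause_min_s", 0.4),
        ("p_consecutive", 1.0),
        ("qrs_suppression", 1.5),
        ("noise_sd_mV", -0.1),
    ])
    def test_invalid_configs_rejected(self, field, value):
        with pytest.raises(ConfigError):
            SimConfig(**{field: value})


class TestRender:
    def test_peak_equals_r_amplitude_at_qrs_centre(self):
        cfg = SimConfig(duration_s=2.0, noise_sd_mV=0.0, wander_amp_mV=0.0, seed=1)
        trace, truth = simulate_recording(cfg)
        p0 = truth.p_times_s[0]
        qc = p0 + cfg.pr_interval_s + cfg.qrs_duration_s / 2.0
        lo, hi = int((p0 - 0.05) * cfg.fs), int((qc + 0.1) * cfg.fs)
        seg = trace.voltage[lo:hi]
        i = lo + int(np.argmax(seg))
        assert abs(i - round(qc * cfg.fs)) <= 1
        assert seg.max() == pytest.approx(cfg.r_amp_mV, abs=1e-3)

    def test_qrs_suppression_flips_peak_ratio(self):
        # R/P peak ratio ~5.5 at WT amplitudes, ~0.55 at tenfold suppression
        for supp, expected in [(1.0, 0.248 / 0.045), (0.1, 0.0248 / 0.045)]:
            cfg = SimConfig(duration_s=4.0, noise_sd_mV=0.0, wander_amp_mV=0.0,
                            qrs_suppression=supp, seed=2)
            trace, truth = simulate_recording(cfg)
            p0 = truth.p_times_s[1]
            qc = p0 + cfg.pr_interval_s + cfg.qrs_duration_s / 2.0
            p_peak = trace.voltage[int((p0 - 0.02) * cfg.fs):int((p0 + 0.02) * cfg.fs)].max()
            r_peak = trace.voltage[int((qc - 0.02) * cfg.fs):int((qc + 0.02) * cfg.fs)].max()
            assert r_peak / p_peak == pytest.approx(expected, rel=0.15)

    def test_trace_length_is_duration_times_fs(self):
        cfg = SimConfig(duration_s=6.0, seed=3)
        trace, _ = simulate_recording(cfg)
        assert trace.n_samples == int(6.0 * cfg.fs)

    def test_noise_only_rms_matches_noise_sd(self):
        cfg = SimConfig(p_amp_mV=0, r_amp_mV=0, t_amp_mV=0, wander_amp_mV=0,
                        noise_sd_mV=0.01, duration_s=30.0, seed=5)
        trace, _ = simulate_recording(cfg)
        rms = float(np.sqrt(np.mean(trace.voltage**2)))
        assert rms == pytest.approx(0.01, rel=0.05)

    def test_overlapping_beats_rejected(self):
        cfg = SimConfig(seed=1)
        truth = generate_beat_schedule(cfg)
        squeezed = truth.p_times_s.copy()
        squeezed[1] = squeezed[0] + 0.05  # < PR + QRS
        truth.p_times_s = np.sort(squeezed)
        with pytest.raises(ConfigError):
            render_trace(truth)

    def test_reference_detector_recovers_beat_count(self, wt_default):
        # independent route: raw amplitude threshold, no envelope machinery
        trace, truth = wt_default
        nyq = trace.fs / 2
        sos = signal.butter(2, 1.0 / nyq, btype="high", output="sos")
        flat = signal.sosfiltfilt(sos, trace.voltage)
        peaks, _ = signal.find_peaks(flat, height=0.5 * flat.max(),
                                     distance=int(0.2 * trace.fs))
        assert peaks.size == truth.p_times_s.size


class TestCohort:
    def test_group_sizes_and_labels(self, tmp_path):
        manifest = [
            ("WT", SimConfig.wildtype(duration_s=6.0), 3),
            ("ClassI", SimConfig.class_i(duration_s=6.0), 2),
            ("ClassII", SimConfig.class_ii(duration_s=6.0), 2),
        ]
        pairs = simulate_cohort(manifest, seed=7)
        assert len(pairs) == 7
        assert [tr.group for tr, _ in pairs] == (
            ["WT"] * 3 + ["ClassI"] * 2 + ["ClassII"] * 2
        )

    def test_rerun_is_byte_identical(self, tmp_path):
        manifest = [("WT", SimConfig.wildtype(duration_s=5.0), 2)]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(manifest, seed=3, out_dir=d1)
        simulate_cohort(manifest, seed=3, out_dir=d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_duplicate_subject_ids_rejected(self):
        manifest = [("WT", SimConfig.wildtype(duration_s=5.0), 1),
                    ("WT", SimConfig.wildtype(duration_s=5.0), 1)]
        with pytest.raises(ConfigError):
            simulate_cohort(manifest, seed=1)


class TestGenotyping:
    @pytest.mark.parametrize("genotype,expected", [
        ("+/+", {152}),
        ("+/-", {152, 141}),
        ("-/-", {141}),
    ])
    def test_fragment_lengths(self, genotype, expected):
        assert genotype_fragments(AlleleModel(), genotype) == expected

    def test_null_deletion(self):
        allele = AlleleModel(wt_amplicon_len=200, deletion_len=0)
        assert genotype_fragments(allele, "-/-") == {200}

    def test_eleven_bp_deletion_causes_frameshift(self):
        assert AlleleModel().causes_frameshift
        assert not AlleleModel(deletion_len=9).causes_frameshift

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ConfigError):
            genotype_fragments(AlleleModel(), "+/?")
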