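# Methods

This note documents the models, conventions and numerical choices behind
`zfecg`, in the spirit of a package methods appendix: what is simulated,
how detection and scoring work, which parameters matter, and what the
synthetic validation does and does not establish about real recordings.

## 1. Synthetic ECG model (`zfecg.synth`)

### Rhythm

Interbeat (P-P) intervals are drawn i.i.d. from a normal distribution
N(`mean_pp_s`, `sd_pp_s`²) truncated below at half the mean. The
truncation prevents nonphysically short cycles; its side effect is a small
upward shift of the realized mean and a shrinkage of the realized SD
(about +0.007 s / −0.009 s at mean 0.54 s, SD 0.135 s; negligible at
wild-type parameters). `base_interval_moments` returns the exact
truncated-normal moments, and all parameter-recovery tests compare
against these rather than the nominal arguments — "recovery" means the
pipeline recovers what the generator actually draws.

Sinus-arrest pauses are superimposed as a marked point process: the number
of episodes is Poisson with mean `sa_rate_per_min` × (analyzable span in
minutes); each episode's pause length is uniform on
[`sa_pause_min_s`, `sa_pause_max_s`]; each pause extends into a
consecutive run with probability `p_consecutive` (repeatedly, so run
lengths are geometric). Recording time is reserved for the drawn pauses
before base intervals fill the remainder, and pause runs are inserted as
blocks at uniformly chosen positions in the base interval sequence. Two
consequences are intentional:

- every drawn episode lies inside the recording, so the expected episode
  count per analyzable minute equals the nominal rate (no edge censoring
  of a fixed-duration window), making `sa_rate_per_min` mean exactly what
  the scorer's `episodes_per_min` estimates;
- distinct runs are always separated by at least one normal interval, so
  injected run counts are well-defined ground truth for the
  consecutive-episode scorer.

The schedule starts at half a mean interval, ends where a full P-QRS
complex last fits, and beat times are rounded to the sampling lattice
(truth below 1/`fs` resolution would only add quantization noise to
round-trip comparisons).

### Waveform

Each beat is a sum of five Gaussian bumps: P (FWHM = `qrs_duration_s`/2) at
the scheduled time; a Q/R/S triplet (R sigma = `qrs_duration_s`/4.2, Q and
S at −8% of R, half sigma, ±0.25 durations from the R centre) rescaled so
the summed peak equals `r_amp_mV` × `qrs_suppression` exactly; and a broad
T bump 80 ms after the QRS. The 4.2 divisor is calibrated analytically so
the 10%-of-peak delineation rule recovers the nominal QRS duration on
noiseless beats. White Gaussian noise (`noise_sd_mV`) and sinusoidal
baseline wander (`wander_amp_mV` at `wander_freq_hz`) are added last.

### Phenotype presets (the study conditions)

| parameter | wild type | Class I | Class II |
|---|---|---|---|
| mean P-P (s) | 0.52 | 0.539 | 0.54 |
| SD P-P (s) | 0.074 | 0.103 | 0.10 |
| SA rate (/min) | 0 | 0.56 | 1.6 |
| p_consecutive | 0 | 0.2 | 0.3 |
| P amp (mV) | 0.045 | 0.055 | 0.055 |
| R amp (mV) | 0.248 | 0.063 | 0.063 |
| PR (s) | 0.033 | 0.050 | 0.050 |
| QRS (s) | 0.0512 | 0.0721 | 0.0721 |
| QRS suppression | 1 | 1 | 0.1 |
| noise SD (mV) | 0.005 | 0.005 | 0.010 |

Defaults: fs = 1000 Hz, 60 s duration, pauses uniform on [1.43, 3.0] s
(2.5 s ceiling for Class II). Pause-length statistics for real SA episodes
are not established for this preparation, so the uniform range — above the
1.3 s cutoff, comfortably below the recording length — is a modeling
choice. The Class II SD of 0.10 s is the *base-rhythm* variability; the
overall interval SD of such recordings (pauses included) lands near the
~0.15 s observed in severely affected fish. Class II suppresses QRS and T
amplitudes tenfold and doubles noise, which drops the complex below the
detectability criterion (below). Noise SD (0.005 mV) and wander
(0.05 mV at 0.3 Hz) are chosen to give P-wave SNR ≈ 9 on the low-passed
signal, typical of a clean needle-electrode surface recording.

## 2. Detection (`zfecg.detect`)

All detector mechanics are this package's conventions (the measurements
they automate are classically made by hand). Times are seconds from trace
start, sample indices 0-based, intervals peak-to-peak; amplitudes are peak
minus local isoelectric baseline (median of the 50 ms window 150–200 ms
before the R candidate, measured on a 1 Hz-high-passed signal so wander
cannot rival the small deflections being measured).

**R peaks.** 5–40 Hz band-pass, squared derivative, 60 ms smoothing;
per-sample threshold k=4 × rolling median of the envelope (1 s blocks) with
a floor at 10% of the envelope maximum; candidates refined to the raw local
maximum within ±25 ms. The refractory period is 0.4 × a running median
interbeat estimate (initialized at 0.5 s); candidates inside it are merged
keeping the larger peak-to-baseline amplitude — with Class I morphology
(wide 0.072 s QRS, P 0.055 mV vs R 0.063 mV) the P wave's envelope rivals
the R wave's, and amplitude-based merging is what keeps the detector on
the R stream. Only gaps below 1.5 × the current estimate update the running
interbeat median: SA pauses are rhythm outliers, and letting them inflate
the refractory would swallow genuine beats after a pause cluster. Flat or
all-NaN traces raise a no-signal error.

**P waves.** On a 1–30 Hz band-pass (wide enough to pass the narrow
zebrafish P wave; a 15 Hz ceiling buries it in QRS filter undershoot).
Anchored mode: most prominent positive peak in [r − 0.15 s, r − 0.02 s];
boundary windows are skipped. Standalone mode (no usable QRS): peak
picking with prominence ≥ k_p=4 × rolling MAD (2 s blocks) and a 0.3 s
refractory, followed by a second-pass height prune (drop candidates below
35% of the candidate median height) — bandlimited noise bumps inside long
SA pauses can pass a pure prominence rule and would split pauses,
deflating the episode rate. Peak times are refined on a detrended,
7 ms-smoothed signal: the band-passed peak is tilted a sample or two by
QRS ringing, while the raw detrended peak jitters under wideband noise.
Detection is amplitude-scale invariant by construction (all thresholds
are relative).

**QRS delineation.** Walking outward from R, the on/offset is the first
sample where |v − baseline| stays below 10% of |R − baseline| for ≥ 4 ms;
beats with no such stretch within 0.15 s are flagged and excluded from
duration averages.

**Pathway selection** (`RhythmAnalysis`). The QRS-anchored pathway is
accepted when ≥ 3 R peaks exist, ≥ 80% of them have an anchored P, and the
P-to-R offsets have a median absolute deviation ≤ 8 ms; otherwise the fit
falls back to standalone P detection with `qrs_detected = False`
everywhere. The dispersion guard is the load-bearing one: on
QRS-suppressed recordings the R detector latches onto the P waves
themselves and the "P" candidates found before them are filter-ringing
lobes or noise, whose offsets scatter an order of magnitude wider
(≥ 14 ms MAD in simulation) than a genuine PR interval (≤ 3.5 ms).

## 3. Indices, classification, SA scoring

Heart rate is defined as 60/mean(P-P), so HR × mean(P-P) = 60 exactly;
the SD uses the n−1 denominator. The PR interval is measured P-peak to
QRS-onset: the observed wild-type value (~0.033 s) is too short for
P-onset conventions at this species' rates, and the convention is
configurable in principle via the delineator outputs. The amplitude ratio
is reported as P/R (dimensionless, < 1 when R dominates). When no beat
carries a QRS, the QRS-dependent fields are absent (None), never zero.
Group tables average per-recording indices, not pooled beats, so a group
P/R need not equal the ratio of group mean amplitudes.

Long beats are intervals above mean + 2σ of the same recording.

**Classification**: Class II iff QRS detectability (fraction of beats with
a delineated QRS) < 0.5, or the mean R amplitude is below 3 × the noise
floor (MAD of the high-passed trace outside ±[−60, +300] ms beat windows);
else Class I. On default-parameter synthetic cohorts this is 100% accurate
by a wide margin (wild-type/Class I detectability ≥ 0.6 with R ≫ noise;
Class II detectability 0).

**SA scoring**: definitive cutoff = fold × normal mean interval (2.5 ×
0.52 s = 1.3 s); screening cutoff 1.0 s (reported, never entering
prevalence). One episode per long interval regardless of its length.
Consecutive incidences are maximal runs of ≥ 2 adjacent episode intervals,
counted once per run by default (`consecutive_unit="episodes"` counts
members instead — the per-minute unit for consecutive episodes is
genuinely ambiguous in common usage). Frequencies divide by the analyzed
span (first to last beat) in minutes. Cohort prevalence averages
per-fish rates, then across fish (the pooled-minutes alternative is a
one-line change and documented here for explicitness). The human
convention (2 s definitive pause at 60–100 bpm resting rates) is an
analogy only; the fish cutoff is always derived or set explicitly.

## 4. Statistics

Group comparisons use the classical pooled-variance unpaired Student
t-test (df = nₐ + n_b − 2, two-sided), with Welch's variant behind a flag;
identical constant samples return t = 0, p = 1, and degenerate unequal
constants raise rather than emit NaN. No multiple-testing correction is
applied to the index panel. qPCR relative expression follows 2^(−ΔΔCt)
(log₂ fold = −ΔΔCt exactly); ΔF/F₀ and the ventricular/atrial surface-area
ratio are elementwise closed forms with positivity checks.

## 5. What the synthetic validation shows — and what it does not

Passing tests establish that the pipeline is internally coherent: exact
noiseless round trips (beat counts, intervals to 1/fs), ≥ 95% standalone
P recall at doubled noise, episode/run counts equal to injected truth,
unbiased recovery of rhythm moments and episode rates over replicate
cohorts, and 100% class separation at the preset parameters. The
generator's morphology is five Gaussian bumps with stationary noise and a
single sinusoidal wander component; real recordings add electrode motion,
respiration artifacts, amplitude drift, ectopy and waveform variability
that none of these tests exercise. Detector thresholds (k = 4, k_p = 4,
band edges, refractory constants) were chosen to satisfy the
simulator-oracle tests at default noise and should be revisited against
manually annotated real traces before use on laboratory data.

Numerical conventions: zero-phase (forward-backward) Butterworth filters
throughout, so no fiducial is phase-shifted; block statistics (medians,
MADs) are linearly interpolated to per-sample resolution; ties in peak
refinement resolve to the earliest sample (`argmax`); recordings shorter
than 2 s, flat, or with fewer than 2 beats raise typed errors rather than
returning empty results.

## 6. Problem sizes

The stochastic validations run at sizes chosen to make their Monte-Carlo
error small against the effects tested: 200 replicate schedules for count
consistency, 1000 for injection-rate recovery, 50 recordings × 2
configurations for moment recovery, 50 × 3 noise levels × 20 s for the
noise-monotonicity check, and 50 one-minute recordings for the in-suite
Class II frequency recovery. The acceptance script enlarges the Class II
cohort to 400 one-minute recordings, pinning the mean episode rate to a
standard error of ~0.06/min.
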