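"""Synthetic adult-zebrafish ECG generator with ground-truth annotations.

The rhythm model draws interbeat (P-P) intervals from a truncated normal
(lower bound half the mean, preventing nonphysical short cycles) and
superimposes sinus-arrest (SA) pauses: a Poisson number of episodes per
recording is drawn, with pause lengths uniform on a configured range, and
each pause may extend into a consecutive run with a geometric continuation
probability. Recording time is reserved for the drawn pauses before the
base rhythm fills the remainder, so the expected episode count per
recorded minute equals the nominal rate. The waveform model renders each beat as a sum of
Gaussian bumps — P wave, Q/R/S triplet, T wave — plus white measurement
noise and sinusoidal baseline wander.

Three phenotype presets mirror the cohorts under study:

* ``SimConfig.wildtype``  — regular rhythm near 115 bpm (mean P-P 0.52 s,
  SD 0.074 s), prominent R wave (0.248 mV), no SA.
* ``SimConfig.class_i``   — mutant with distinguishable QRS: reduced R
  amplitude (0.063 mV), prolonged PR (0.050 s) and QRS (0.0721 s),
  increased rhythm variability, occasional SA pauses.
* ``SimConfig.class_ii``  — mutant without a distinguishable QRS: QRS/T
  amplitudes suppressed tenfold, noise doubled, frequent SA pauses
  (1.6 episodes/min) including consecutive runs.

The module also houses the genotyping-amplicon arithmetic for the
11-nucleotide frameshift deletion allele (152 bp wild-type fragment,
141 bp mutant fragment).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import ECGTrace
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "AlleleModel",
    "generate_beat_schedule",
    "render_trace",
    "simulate_recording",
    "simulate_cohort",
    "genotype_fragments",
    "base_interval_moments",
]

# Gaussian-bump geometry: an R bump of width sigma = duration / _QRS_SIGMA_DIV
# crosses 10% of its peak at +/- duration/2 once the -8% Q and S side lobes
# (half-width, at -/+ 0.25 duration) are added, so the 10%-threshold
# delineation rule recovers the nominal QRS duration on noiseless beats.
_QRS_SIGMA_DIV = 4.2
_QS_FRAC = 0.08
_QS_OFFSET = 0.25
# P and T bumps: "width" parameters are full widths at half maximum.
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of rhythm, morphology and noise, with seed.

    Units: seconds for times/intervals, Hz for rates, mV for amplitudes.
    ``qrs_suppression`` multiplies the QRS and T amplitudes; values well
    below 1 emulate recordings whose ventricular deflection is buried in
    noise (Class II morphology).
    """

    duration_s: float = 60.0
    fs: float = 1000.0
    mean_pp_s: float = 0.52
    sd_pp_s: float = 0.074
    sa_rate_per_min: float = 0.0
    sa_pause_min_s: float = 1.43
    sa_pause_max_s: float = 3.0
    p_consecutive: float = 0.0
    p_amp_mV: float = 0.045
    r_amp_mV: float = 0.248
    t_amp_mV: float = 0.04
    pr_interval_s: float = 0.033
    qrs_duration_s: float = 0.0512
    qrs_suppression: float = 1.0
    noise_sd_mV: float = 0.005
    wander_amp_mV: float = 0.05
    wander_freq_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigError("duration_s must be positive")
        if self.fs < 100:
            raise ConfigError("fs must be >= 100 Hz")
        if not 0 < self.sd_pp_s < self.mean_pp_s:
            raise ConfigError("need 0 < sd_pp_s < mean_pp_s")
        if not self.sa_pause_min_s > self.mean_pp_s:
            raise ConfigError("sa_pause_min_s must exceed mean_pp_s")
        if self.sa_pause_max_s < self.sa_pause_min_s:
            raise ConfigError("sa_pause_max_s must be >= sa_pause_min_s")
        if not 0 <= self.p_consecutive < 1:
            raise ConfigError("p_consecutive must be in [0, 1)")
        if not 0 <= self.qrs_suppression <= 1:
            raise ConfigError("qrs_suppression must be in [0, 1]")
        for name in ("p_amp_mV", "r_amp_mV", "t_amp_mV", "noise_sd_mV", "wander_amp_mV"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        # Reject configurations whose expected total pause time cannot fit
        # into the recording.
        mean_pause = 0.5 * (self.sa_pause_min_s + self.sa_pause_max_s)
        expected_n = self.sa_rate_per_min * self.duration_s / 60.0
        if self.p_consecutive > 0:
            expected_n /= 1.0 - self.p_consecutive
        if expected_n * mean_pause > self.duration_s:
            raise ConfigError("expected SA pause time exceeds recording duration")

    # phenotype presets -------------------------------------------------

    @classmethod
    def wildtype(cls, **overrides) -> "SimConfig":
        """Regular sinus rhythm near 115 bpm with a prominent QRS."""
        return cls(**overrides)

    @classmethod
    def class_i(cls, **overrides) -> "SimConfig":
        """Mutant with distinguishable QRS: small, slow ventricular complex."""
        params = dict(
            mean_pp_s=0.539,
            sd_pp_s=0.103,
            sa_rate_per_min=0.56,
            p_consecutive=0.2,
            p_amp_mV=0.055,
            r_amp_mV=0.063,
            pr_interval_s=0.050,
            qrs_duration_s=0.0721,
            qrs_suppression=1.0,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def class_ii(cls, **overrides) -> "SimConfig":
        """Mutant without distinguishable QRS: suppressed complex, frequent SA."""
        params = dict(
            mean_pp_s=0.54,
            sd_pp_s=0.10,
            sa_rate_per_min=1.6,
            sa_pause_max_s=2.5,
            p_consecutive=0.3,
            p_amp_mV=0.055,
            r_amp_mV=0.063,
            pr_interval_s=0.050,
            qrs_duration_s=0.0721,
            qrs_suppression=0.1,
            noise_sd_mV=0.01,
        )
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Truth channel for one simulated recording."""

    p_times_s: np.ndarray
    injected_pause_indices: list[int]
    class_label: str
    config: SimConfig

    def __post_init__(self) -> None:
        self.p_times_s = np.asarray(self.p_times_s, dtype=float)
        if self.p_times_s.size > 1 and not np.all(np.diff(self.p_times_s) > 0):
            raise ConfigError("ground-truth beat times must be strictly increasing")

    @property
    def intervals_s(self) -> np.ndarray:
        return np.diff(self.p_times_s)

    @property
    def injected_run_count(self) -> int:
        """Number of maximal runs of >= 2 consecutive injected pauses."""
        idx = sorted(self.injected_pause_indices)
        runs = 0
        i = 0
        while i < len(idx):
            j = i
            while j + 1 < len(idx) and idx[j + 1] == idx[j] + 1:
                j += 1
            if j > i:
                runs += 1
            i = j + 1
        return runs

    def to_json(self) -> str:
        return json.dumps(
            {
                "p_times_s": [round(float(t), 9) for t in self.p_times_s],
                "injected_pause_indices": [int(i) for i in self.injected_pause_indices],
                "class_label": self.class_label,
                "config": self.config.to_dict(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            p_times_s=np.asarray(d["p_times_s"], dtype=float),
            injected_pause_indices=list(d["injected_pause_indices"]),
            class_label=d["class_label"],
            config=SimConfig(**d["config"]),
        )


def base_interval_moments(config: SimConfig) -> tuple[float, float]:
    """Exact (mean, SD) of the truncated-normal base interval distribution.

    The generator truncates at 0.5 x mean_pp_s from below, which shifts the
    realised moments slightly away from the nominal (mean_pp_s, sd_pp_s);
    recovery tests compare against these exact values.
    """
    a = (0.5 * config.mean_pp_s - config.mean_pp_s) / config.sd_pp_s
    mean, var = stats.truncnorm.stats(
        a, np.inf, loc=config.mean_pp_s, scale=config.sd_pp_s, moments="mv"
    )
    return float(mean), float(np.sqrt(var))


def generate_beat_schedule(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Draw a ground-truth beat schedule for one recording.

    Base intervals come from a truncated normal. A Poisson number of SA
    episodes (rate ``sa_rate_per_min`` per minute of recording) is drawn,
    each a uniform pause that extends into a consecutive run with
    probability ``p_consecutive`` (repeatedly, giving geometric run
    lengths). Time is reserved for the drawn pauses before the base rhythm
    fills the remainder, so every drawn episode appears inside the
    recording and the expected episode count per recorded minute equals the
    nominal rate. The schedule starts at half a mean interval and ends
    where a full P-QRS complex last fits.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    t0 = 0.5 * config.mean_pp_s
    margin = config.pr_interval_s + config.qrs_duration_s + 0.02
    budget = config.duration_s - t0 - margin
    if budget <= config.mean_pp_s:
        raise ConfigError("recording too short for even one interval")

    # SA episodes: Poisson count of runs, geometric run lengths. The rate
    # refers to the analyzable rhythm span (first to last beat), matching
    # the per-minute normalization used when scoring recordings.
    runs: list[list[float]] = []
    n_runs = rng.poisson(config.sa_rate_per_min * budget / 60.0)
    for _ in range(n_runs):
        run = [rng.uniform(config.sa_pause_min_s, config.sa_pause_max_s)]
        while config.p_consecutive > 0 and rng.random() < config.p_consecutive:
            run.append(rng.uniform(config.sa_pause_min_s, config.sa_pause_max_s))
        runs.append(run)
    total_pause = sum(sum(r) for r in runs)
    # drop whole runs (rare) if the drawn pause time cannot leave room for
    # at least a couple of normal cycles
    while runs and total_pause > budget - 2 * config.mean_pp_s:
        total_pause -= sum(runs.pop())

    # base rhythm fills the remaining time
    a = -0.5 * config.mean_pp_s / config.sd_pp_s  # z-score of the 0.5*mean bound
    n_draw = int(np.ceil((budget - total_pause) / config.mean_pp_s * 2)) + 20
    base = stats.truncnorm.rvs(
        a, np.inf, loc=config.mean_pp_s, scale=config.sd_pp_s,
        size=n_draw, random_state=rng,
    )
    n_base = int(np.searchsorted(np.cumsum(base), budget - total_pause))
    base = base[:n_base]

    # interleave: each run is inserted as a block at a distinct base slot
    intervals: list[float] = []
    pause_idx: list[int] = []
    if runs:
        slots = np.sort(rng.choice(n_base + 1, size=min(len(runs), n_base + 1),
                                   replace=False))
        prev = 0
        for slot, run in zip(slots, runs):
            intervals.extend(base[prev:slot])
            pause_idx.extend(range(len(intervals), len(intervals) + len(run)))
            intervals.extend(run)
            prev = int(slot)
        intervals.extend(base[prev:])
    else:
        intervals = list(base)

    p_times = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    # truth times live on the sampling lattice: rendering and detection both
    # operate at 1/fs resolution, so sub-sample truth would only add
    # quantization noise to round-trip comparisons
    p_times = np.round(p_times * config.fs) / config.fs
    if p_times.size < 2:
        raise ConfigError("no beats fit into the recording duration")

    label = "II" if config.qrs_suppression < 0.5 else "I"
    return GroundTruth(
        p_times_s=p_times,
        injected_pause_indices=pause_idx,
        class_label=label,
        config=config,
    )


def _add_gauss(voltage: np.ndarray, fs: float, center_s: float,
               amp: float, sigma_s: float) -> None:
    """Add amp * exp(-(t-c)^2 / 2 sigma^2) over a +/- 5 sigma window, in place."""
    if amp == 0.0:
        return
    lo = max(0, int(np.floor((center_s - 5 * sigma_s) * fs)))
    hi = min(voltage.size, int(np.ceil((center_s + 5 * sigma_s) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    voltage[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def render_trace(
    truth: GroundTruth,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "",
    group: str = "",
) -> ECGTrace:
    """Render a beat schedule into a sampled voltage trace.

    Each beat is the sum of five Gaussian bumps: P (amplitude ``p_amp_mV``,
    FWHM = qrs_duration/2) at the scheduled P time; Q, R, S centred
    pr_interval + qrs_duration/2 after P with total 10%-threshold support
    equal to ``qrs_duration_s`` and summed peak exactly
    ``r_amp_mV x qrs_suppression``; and a broad T bump after the QRS.
    White noise and sinusoidal baseline wander are added last.
    """
    cfg = truth.config
    if truth.p_times_s.size == 0:
        raise ConfigError("cannot render an empty beat schedule")
    min_iv = float(np.min(truth.intervals_s)) if truth.p_times_s.size > 1 else np.inf
    if min_iv < cfg.pr_interval_s + cfg.qrs_duration_s:
        raise ConfigError("beats overlap: interval shorter than PR + QRS duration")
    if rng is None:
        # decoupled from the schedule stream so morphology noise does not
        # depend on how many beats were drawn
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))

    n = int(round(cfg.duration_s * cfg.fs))
    v = np.zeros(n)

    sigma_p = (cfg.qrs_duration_s / 2.0) * _FWHM_TO_SIGMA
    sigma_r = cfg.qrs_duration_s / _QRS_SIGMA_DIV
    sigma_qs = sigma_r / 2.0
    # rescale so the summed waveform peak at the R centre equals r_amp
    corr = 1.0 - 2.0 * _QS_FRAC * np.exp(
        -0.5 * (_QS_OFFSET * cfg.qrs_duration_s / sigma_qs) ** 2
    )
    r_peak = cfg.r_amp_mV * cfg.qrs_suppression
    a_r = r_peak / corr
    t_amp = cfg.t_amp_mV * cfg.qrs_suppression

    for p in truth.p_times_s:
        qrs_c = p + cfg.pr_interval_s + cfg.qrs_duration_s / 2.0
        _add_gauss(v, cfg.fs, p, cfg.p_amp_mV, sigma_p)
        _add_gauss(v, cfg.fs, qrs_c - _QS_OFFSET * cfg.qrs_duration_s,
                   -_QS_FRAC * a_r, sigma_qs)
        _add_gauss(v, cfg.fs, qrs_c, a_r, sigma_r)
        _add_gauss(v, cfg.fs, qrs_c + _QS_OFFSET * cfg.qrs_duration_s,
                   -_QS_FRAC * a_r, sigma_qs)
        _add_gauss(v, cfg.fs, qrs_c + cfg.qrs_duration_s / 2.0 + 0.08,
                   t_amp, 0.035)

    if cfg.noise_sd_mV > 0:
        v += rng.normal(0.0, cfg.noise_sd_mV, size=n)
    if cfg.wander_amp_mV > 0:
        t = np.arange(n) / cfg.fs
        v += cfg.wander_amp_mV * np.sin(2 * np.pi * cfg.wander_freq_hz * t)

    return ECGTrace(voltage=v, fs=cfg.fs, subject_id=subject_id, group=group)


def simulate_recording(
    config: SimConfig, subject_id: str = "", group: str = ""
) -> tuple[ECGTrace, GroundTruth]:
    """Schedule + render one recording from its config seed."""
    rng = np.random.default_rng(config.seed)
    truth = generate_beat_schedule(config, rng)
    trace = render_trace(truth, subject_id=subject_id, group=group)
    return trace, truth


def subject_seed(manifest_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the manifest seed."""
    ss = np.random.SeedSequence([int(manifest_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    manifest: Sequence[tuple[str, SimConfig, int]],
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> list[tuple[ECGTrace, GroundTruth]]:
    """Simulate a labelled cohort of recordings.

    ``manifest`` is a sequence of (group label, config, n subjects). Subject
    seeds derive deterministically from ``seed`` and the running subject
    index, so the cohort is reproducible and order-stable. When ``out_dir``
    is given, each trace is written as CSV + JSON metadata sidecar and each
    truth as JSON (see :mod:`zfecg.io`).
    """
    from . import io as _io  # local import: io depends on core only

    out: list[tuple[ECGTrace, GroundTruth]] = []
    seen_ids: set[str] = set()
    index = 0
    for label, config, n in manifest:
        if n < 1:
            raise ConfigError(f"group {label!r} must have n >= 1")
        for k in range(n):
            sid = f"{label}_{k + 1:02d}"
            if sid in seen_ids:
                raise ConfigError(f"duplicate subject id {sid!r}")
            seen_ids.add(sid)
            cfg = config.replace(seed=subject_seed(seed, index))
            trace, truth = simulate_recording(cfg, subject_id=sid, group=label)
            out.append((trace, truth))
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                _io.write_trace(trace, out_dir / f"{sid}.csv", config=cfg)
                (out_dir / f"{sid}.truth.json").write_text(truth.to_json())
            index += 1
    return out


@dataclass(frozen=True)
class AlleleModel:
    """Deletion allele for PCR genotyping arithmetic.

    Defaults describe an 11-nucleotide exon-1 deletion: 152 bp wild-type
    amplicon, 141 bp mutant amplicon, frameshift after the 10th residue.
    """

    wt_amplicon_len: int = 152
    deletion_len: int = 11
    frameshift_after_residue: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.deletion_len < self.wt_amplicon_len:
            raise ConfigError("deletion must be shorter than the amplicon")

    @property
    def causes_frameshift(self) -> bool:
        return self.deletion_len % 3 != 0

    @property
    def mutant_amplicon_len(self) -> int:
        return self.wt_amplicon_len - self.deletion_len


def genotype_fragments(allele: AlleleModel, genotype: str) -> set[int]:
    """PCR fragment lengths (bp) resolved on a gel for one genotype.

    ``genotype`` is one of ``"+/+"``, ``"+/-"``, ``"-/-"``.
    """
    wt, mut = allele.wt_amplicon_len, allele.mutant_amplicon_len
    table = {"+/+": {wt}, "-/-": {mut}, "+/-": {wt, mut}}
    try:
        return table[genotype]
    except KeyError:
        raise ConfigError(f"unknown genotype code {genotype!r}") from None
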