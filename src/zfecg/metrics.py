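"""Rhythm indices, long-beat flagging, Poincaré descriptors, morphology class.

Conventions: heart rate is defined from the mean P-P interval
(``hr_bpm = 60 / mean_pp_s``, exactly); the sample SD uses the n-1
denominator; the PR interval runs from the P peak to the QRS onset; the
amplitude ratio is P/R (values below 1 for a dominant R wave). Beats
lacking a QRS are excluded from QRS-dependent means, and when no beat
carries a QRS those fields are absent (None), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import BeatSet, IntervalSeries
from .errors import InsufficientBeatsError, InsufficientDataError

__all__ = [
    "ECGIndices",
    "PoincarePairs",
    "pp_intervals",
    "compute_indices",
    "flag_long_beats",
    "classify_ecg",
    "poincare_pairs",
]


@dataclass
class ECGIndices:
    """Per-recording ECG indices (Nones where the QRS stream is absent)."""

    hr_bpm: float
    mean_pp_s: float
    sd_pp_s: float
    mean_p_amp_mV: float
    mean_r_amp_mV: Optional[float]
    p_over_r_ratio: Optional[float]
    mean_pr_s: Optional[float]
    mean_qrs_s: Optional[float]
    qrs_detectability: float
    ecg_class: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "hr_bpm": self.hr_bpm,
            "mean_pp_s": self.mean_pp_s,
            "sd_pp_s": self.sd_pp_s,
            "mean_p_amp_mV": self.mean_p_amp_mV,
            "mean_r_amp_mV": self.mean_r_amp_mV,
            "p_over_r_ratio": self.p_over_r_ratio,
            "mean_pr_s": self.mean_pr_s,
            "mean_qrs_s": self.mean_qrs_s,
            "qrs_detectability": self.qrs_detectability,
            "ecg_class": self.ecg_class,
        }


@dataclass
class PoincarePairs:
    """Consecutive-interval pairs (IBI_{n-1}, IBI_n) with SD1/SD2 descriptors.

    SD1 — dispersion perpendicular to the identity line, the beat-to-beat
    component: SD of (IBI_n - IBI_{n-1}) / sqrt(2). SD2 — dispersion along
    the identity line: SD of (IBI_n + IBI_{n-1}) / sqrt(2).
    """

    pairs: np.ndarray  # shape (m-1, 2)
    sd1: float
    sd2: float


def pp_intervals(beats: BeatSet) -> IntervalSeries:
    """Successive P-peak differences of one recording.

    The analyzed duration is the span from first to last P peak (in
    minutes), so per-minute frequencies refer to analyzed rhythm time.
    """
    times = beats.p_times_s
    if times.size < 2:
        raise InsufficientBeatsError(
            f"need >= 2 beats for intervals, got {times.size}"
        )
    pp = np.diff(times)
    return IntervalSeries(pp_s=pp, recording_duration_min=(times[-1] - times[0]) / 60.0)


def compute_indices(beats: BeatSet, intervals: IntervalSeries) -> ECGIndices:
    """Compute the per-recording index panel from beats and intervals."""
    if len(intervals) == 0:
        raise InsufficientDataError("interval series is empty")
    pp = intervals.pp_s
    mean_pp = float(np.mean(pp))
    sd_pp = float(np.std(pp, ddof=1)) if pp.size > 1 else 0.0

    p_amps = beats.p_amps_mV
    qrs_beats = [b for b in beats.beats if b.qrs_detected]
    if qrs_beats:
        mean_r = float(np.mean([b.r_amp_mV for b in qrs_beats]))
        mean_pr = float(np.mean([b.qrs_onset_s - b.p_time_s for b in qrs_beats]))
        mean_qrs = float(np.mean([b.qrs_offset_s - b.qrs_onset_s for b in qrs_beats]))
        mean_p = float(np.mean(p_amps)) if p_amps.size else float("nan")
        p_over_r = mean_p / mean_r if mean_r != 0 else None
    else:
        mean_r = mean_pr = mean_qrs = p_over_r = None
        mean_p = float(np.mean(p_amps)) if p_amps.size else float("nan")

    return ECGIndices(
        hr_bpm=60.0 / mean_pp,
        mean_pp_s=mean_pp,
        sd_pp_s=sd_pp,
        mean_p_amp_mV=mean_p,
        mean_r_amp_mV=mean_r,
        p_over_r_ratio=p_over_r,
        mean_pr_s=mean_pr,
        mean_qrs_s=mean_qrs,
        qrs_detectability=beats.qrs_fraction,
    )


def flag_long_beats(intervals: IntervalSeries) -> np.ndarray:
    """Indices of intervals exceeding mean + 2 sigma of the same recording."""
    pp = intervals.pp_s
    if pp.size < 3:
        raise InsufficientDataError("long-beat flagging needs >= 3 intervals")
    thr = np.mean(pp) + 2.0 * np.std(pp, ddof=1)
    return np.flatnonzero(pp > thr)


def classify_ecg(indices: ECGIndices, noise_floor_mV: float) -> str:
    """Class II iff the QRS stream is unusable: detectability below one half,
    or a mean R amplitude under 3x the noise floor; otherwise Class I."""
    if indices.qrs_detectability < 0.5 or indices.mean_r_amp_mV is None:
        return "II"
    if indices.mean_r_amp_mV < 3.0 * noise_floor_mV:
        return "II"
    return "I"


def poincare_pairs(intervals: IntervalSeries) -> PoincarePairs:
    """Consecutive-interval scatter pairs and SD1/SD2 ellipse descriptors."""
    pp = intervals.pp_s
    if pp.size < 2:
        raise InsufficientDataError("Poincaré analysis needs >= 2 intervals")
    prev, cur = pp[:-1], pp[1:]
    sd1 = float(np.std((cur - prev) / np.sqrt(2.0), ddof=1)) if pp.size > 2 else 0.0
    sd2 = float(np.std((cur + prev) / np.sqrt(2.0), ddof=1)) if pp.size > 2 else 0.0
    return PoincarePairs(pairs=np.column_stack([prev, cur]), sd1=sd1, sd2=sd2)
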