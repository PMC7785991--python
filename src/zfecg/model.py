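"""Model/Results facade over the detection-and-scoring pipeline.

``RhythmAnalysis`` is built from one ECG trace (or directly from a
time/voltage DataFrame); ``fit()`` runs fiducial detection, interval
extraction, index computation, morphology classification and sinus-arrest
scoring, and returns a ``RhythmResults`` carrying the estimates, a
``summary()`` table and plotting helpers.

Pathway selection
-----------------
The fit first attempts the QRS-anchored pathway (R detection, then P
search in a window before each R). It falls back to standalone P-wave
detection when the R stream is unusable: too few R peaks, too few anchored
P waves, or P-to-R offsets too dispersed. The dispersion guard matters
because on QRS-suppressed recordings the R detector latches onto P waves
themselves, and the "P" candidates found before them are noise bumps with
near-uniform offsets — a genuine PR interval is tightly clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import detect, metrics, sa
from .core import BeatSet, ECGTrace, IntervalSeries
from .detect import DetectorParams
from .errors import InsufficientBeatsError

__all__ = ["RhythmAnalysis", "RhythmResults"]

# anchored pathway accepted when >= this fraction of R peaks have a P and
# the P-to-R offsets have MAD below _PR_MAD_MAX_S
_ANCHOR_MIN_FRAC = 0.8
_PR_MAD_MAX_S = 0.008


@dataclass
class RhythmResults:
    """Fitted rhythm analysis of one recording."""

    trace: ECGTrace
    beats: BeatSet
    intervals: IntervalSeries
    indices: metrics.ECGIndices
    sa_report: sa.SAReport
    poincare: metrics.PoincarePairs
    long_beat_indices: np.ndarray
    noise_floor_mV: float
    pathway: str  # "anchored" or "standalone"

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    def summary(self) -> str:
        """Human-readable per-recording summary table."""
        ix = self.indices
        sar = self.sa_report

        def fmt(x, nd=3):
            return "   --" if x is None else f"{x:.{nd}f}"

        lines = [
            "Zebrafish ECG rhythm analysis",
            "=" * 46,
            f"subject: {self.trace.subject_id or '-'}   group: {self.trace.group or '-'}",
            f"pathway: {self.pathway}   beats: {self.n_beats}   "
            f"duration: {self.intervals.recording_duration_min:.2f} min",
            "-" * 46,
            f"heart rate            {ix.hr_bpm:8.1f} bpm",
            f"mean P-P interval     {ix.mean_pp_s:8.3f} s",
            f"SD of P-P interval    {ix.sd_pp_s:8.3f} s",
            f"mean P amplitude      {ix.mean_p_amp_mV:8.3f} mV",
            f"mean R amplitude      {fmt(ix.mean_r_amp_mV):>8} mV",
            f"P/R amplitude ratio   {fmt(ix.p_over_r_ratio):>8}",
            f"mean PR interval      {fmt(ix.mean_pr_s):>8} s",
            f"mean QRS duration     {fmt(ix.mean_qrs_s, 4):>8} s",
            f"QRS detectability     {ix.qrs_detectability:8.2f}",
            f"ECG class             {ix.ecg_class:>8}",
            "-" * 46,
            f"SA cutoff (definitive){sar.definitive_cutoff_s:8.2f} s"
            f"   (screening {sar.screening_cutoff_s:.2f} s)",
            f"SA episodes           {sar.n_episodes:8d}"
            f"   ({sar.episodes_per_min:.2f} /min)",
            f"consecutive SA runs   {sar.n_consecutive_runs:8d}"
            f"   ({sar.consecutive_runs_per_min:.2f} /min)",
            f"long beats (>m+2s)    {self.long_beat_indices.size:8d}",
            f"Poincare SD1 / SD2    {self.poincare.sd1:8.3f} / {self.poincare.sd2:.3f} s",
        ]
        return "\n".join(lines)

    def beats_frame(self) -> pd.DataFrame:
        """Per-beat fiducial table (one row per beat)."""
        rows = []
        for i, b in enumerate(self.beats.beats):
            rows.append({
                "beat_idx": i,
                "p_time_s": b.p_time_s,
                "p_amp_mV": b.p_amp_mV,
                "qrs_onset_s": b.qrs_onset_s,
                "r_time_s": b.r_time_s,
                "r_amp_mV": b.r_amp_mV,
                "qrs_offset_s": b.qrs_offset_s,
                "qrs_detected": b.qrs_detected,
            })
        return pd.DataFrame(rows)

    def plot_poincare(self, ax=None):
        """Scatter of consecutive intervals with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pairs = self.poincare.pairs
        ax.scatter(pairs[:, 0], pairs[:, 1], s=8, alpha=0.6)
        lim = max(1.5, float(pairs.max()) * 1.1)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="identity")
        ax.axhline(self.sa_report.definitive_cutoff_s, color="r", lw=0.8,
                   label=f"SA cutoff {self.sa_report.definitive_cutoff_s:g} s")
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
        ax.set_xlabel("IBI$_{n-1}$ (s)")
        ax.set_ylabel("IBI$_n$ (s)")
        ax.set_title(self.trace.subject_id or "Poincaré")
        ax.legend(fontsize=7)
        return ax

    def plot_trace(self, ax=None, t_range=None):
        """Trace with detected fiducials; long beats marked with arrows."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        t = self.trace.time_s
        ax.plot(t, self.trace.voltage, lw=0.5, color="0.2")
        pt = self.beats.p_times_s
        ax.plot(pt, np.interp(pt, t, self.trace.voltage), "b.", ms=4, label="P")
        rt = [b.r_time_s for b in self.beats.beats if b.qrs_detected]
        if rt:
            ax.plot(rt, np.interp(rt, t, self.trace.voltage), "r^", ms=4, label="R")
        for i in self.long_beat_indices:
            ax.annotate("", xy=(pt[i + 1], float(self.trace.voltage.max())),
                        xytext=(pt[i + 1], float(self.trace.voltage.max()) * 1.3),
                        arrowprops=dict(arrowstyle="->", color="r"))
        if t_range is not None:
            ax.set_xlim(*t_range)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mV")
        ax.legend(fontsize=7, loc="upper right")
        return ax


class RhythmAnalysis:
    """Rhythm model for one single-lead zebrafish ECG recording.

    Parameters
    ----------
    trace : ECGTrace
        The recording to analyze.
    params : DetectorParams, optional
        Detector settings.
    definitive_cutoff_s, screening_cutoff_s : float
        SA cutoffs passed to the scorer (1.3 s definitive, 1.0 s
        screening by default).
    """

    def __init__(
        self,
        trace: ECGTrace,
        params: DetectorParams = DetectorParams(),
        definitive_cutoff_s: float = 1.3,
        screening_cutoff_s: float = 1.0,
    ) -> None:
        self.trace = trace
        self.params = params
        self.definitive_cutoff_s = definitive_cutoff_s
        self.screening_cutoff_s = screening_cutoff_s

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, fs: Optional[float] = None,
        subject_id: str = "", group: str = "", **kwargs
    ) -> "RhythmAnalysis":
        """Build from a two-column time/voltage DataFrame.

        Expects columns ``time_s`` and ``voltage_mV``; the sampling rate is
        inferred from the time column unless given.
        """
        t = frame["time_s"].to_numpy(dtype=float)
        v = frame["voltage_mV"].to_numpy(dtype=float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        trace = ECGTrace(voltage=v, fs=fs, subject_id=subject_id, group=group)
        return cls(trace, **kwargs)

    # ------------------------------------------------------------------

    def _detect(self) -> tuple[BeatSet, str]:
        trace, params = self.trace, self.params
        try:
            r_list = detect.detect_r_peaks(trace, params)
        except Exception:
            r_list = []

        if len(r_list) >= 3:
            p_anchored = detect.detect_p_waves(trace, r_list, params)
            if len(p_anchored) >= _ANCHOR_MIN_FRAC * len(r_list):
                # pair offsets: genuine PR intervals cluster tightly
                p_times = np.array([p for p, _ in p_anchored])
                offs = []
                for r_time, _ in r_list:
                    before = p_times[(p_times < r_time - 0.01)
                                     & (p_times > r_time - 0.25)]
                    if before.size:
                        offs.append(r_time - before[-1])
                offs = np.asarray(offs)
                if offs.size >= 3:
                    mad = float(np.median(np.abs(offs - np.median(offs))))
                    if mad <= _PR_MAD_MAX_S:
                        qrs = detect.delineate_qrs(trace, r_list, params)
                        beats = detect.assemble_beats(
                            p_anchored, r_list, qrs, trace)
                        if len(beats) >= 2:
                            return beats, "anchored"

        p_alone = detect.detect_p_waves(trace, None, params)
        beats = detect.assemble_beats(p_alone, None, None, trace)
        return beats, "standalone"

    def fit(self) -> RhythmResults:
        """Run detection, interval extraction, indices and SA scoring."""
        beats, pathway = self._detect()
        if len(beats) < 2:
            raise InsufficientBeatsError(
                "fewer than 2 beats detected; cannot analyze rhythm")
        intervals = metrics.pp_intervals(beats)
        indices = metrics.compute_indices(beats, intervals)
        noise_floor = detect.estimate_noise_floor(
            self.trace, beats.p_times_s.tolist())
        indices.ecg_class = metrics.classify_ecg(indices, noise_floor)
        sa_report = sa.detect_sa_episodes(
            intervals, self.definitive_cutoff_s, self.screening_cutoff_s)
        poincare = metrics.poincare_pairs(intervals)
        long_idx = (metrics.flag_long_beats(intervals)
                    if len(intervals) >= 3 else np.array([], dtype=int))
        return RhythmResults(
            trace=self.trace,
            beats=beats,
            intervals=intervals,
            indices=indices,
            sa_report=sa_report,
            poincare=poincare,
            long_beat_indices=long_idx,
            noise_floor_mV=noise_floor,
            pathway=pathway,
        )
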