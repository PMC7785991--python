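"""Fiducial detection for single-lead zebrafish ECG.

Two detection streams are provided and may be combined:

* **R peaks** — band-passed (5–40 Hz) squared-derivative envelope with an
  adaptive threshold (k x rolling median of the envelope) and an adaptive
  refractory period (0.4 x running median interbeat interval). Candidates
  closer than the refractory period are merged keeping the larger raw
  peak-to-baseline amplitude, which keeps the detector on the R stream even
  when a wide, low QRS has an envelope comparable to the P wave's.
* **P waves** — on a 1–30 Hz band-passed signal, either anchored in a
  window before each R peak, or standalone prominence-based picking for
  recordings without a usable QRS (the atrial stream is the primary rhythm
  marker in this preparation, so P detection never requires a QRS).

QRS on/offset delineation walks outward from R until the signal stays
within 10% of the R excursion (relative to a pre-beat isoelectric
baseline) for at least 4 ms.

All detector mechanics here (filter bands, thresholds k, refractory rules,
baseline windows) are this module's conventions; amplitudes are reported
peak minus local isoelectric baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import Beat, BeatSet, ECGTrace
from .errors import InsufficientDataError, NoSignalError

__all__ = [
    "DetectorParams",
    "detect_r_peaks",
    "detect_p_waves",
    "delineate_qrs",
    "assemble_beats",
    "estimate_noise_floor",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detector settings (defaults are the package conventions)."""

    r_band_hz: tuple[float, float] = (5.0, 40.0)
    r_threshold_k: float = 4.0
    r_refractory_init_s: float = 0.2
    r_refractory_frac: float = 0.4
    p_band_hz: tuple[float, float] = (1.0, 30.0)
    p_threshold_k: float = 4.0
    p_refractory_s: float = 0.3
    p_window_s: tuple[float, float] = (0.15, 0.02)  # before R: [r-0.15, r-0.02]
    p_height_prune_frac: float = 0.35
    qrs_typical_s: float = 0.06
    qrs_threshold_frac: float = 0.10
    qrs_sustain_s: float = 0.004
    qrs_search_s: float = 0.15
    baseline_window_s: tuple[float, float] = (0.20, 0.15)  # before R


def _check_signal(trace: ECGTrace, min_duration_s: float = 2.0) -> None:
    v = trace.voltage
    if trace.duration_s < min_duration_s:
        raise InsufficientDataError(
            f"trace of {trace.duration_s:.2f} s is shorter than "
            f"{min_duration_s:.0f} s"
        )
    if np.all(np.isnan(v)):
        raise NoSignalError("trace is all NaN")
    finite = v[np.isfinite(v)]
    if finite.size == 0 or np.ptp(finite) == 0.0:
        raise NoSignalError("trace is flat; no signal to detect")


def _bandpass(v: np.ndarray, fs: float, band: tuple[float, float],
              order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = signal.butter(order, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, v)


def _block_stat(x: np.ndarray, fs: float, block_s: float, func) -> np.ndarray:
    """Blockwise robust statistic interpolated back to per-sample length."""
    w = max(1, int(round(block_s * fs)))
    n_blocks = max(1, x.size // w)
    centers = np.empty(n_blocks)
    vals = np.empty(n_blocks)
    for b in range(n_blocks):
        lo = b * w
        hi = x.size if b == n_blocks - 1 else (b + 1) * w
        vals[b] = func(x[lo:hi])
        centers[b] = 0.5 * (lo + hi)
    return np.interp(np.arange(x.size), centers, vals)


def _detrended(v: np.ndarray, fs: float, corner_hz: float = 1.0) -> np.ndarray:
    """Remove baseline wander with a zero-phase 1 Hz high-pass.

    Amplitude measurement and QRS delineation work against a local
    isoelectric baseline whose drift between the baseline window and the
    beat would otherwise rival the small deflections being measured.
    """
    nyq = fs / 2.0
    sos = signal.butter(2, corner_hz / nyq, btype="high", output="sos")
    return signal.sosfiltfilt(sos, v)


def _local_baseline(v: np.ndarray, fs: float, r_idx: int,
                    window_s: tuple[float, float]) -> float:
    """Median of a pre-beat window [r - w0, r - w1]; falls back near edges."""
    lo = r_idx - int(round(window_s[0] * fs))
    hi = r_idx - int(round(window_s[1] * fs))
    if lo < 0:
        lo, hi = 0, max(1, hi)
    if hi <= lo:
        hi = lo + 1
    return float(np.median(v[lo:hi]))


def detect_r_peaks(
    trace: ECGTrace, params: DetectorParams = DetectorParams()
) -> list[tuple[float, float]]:
    """Detect R peaks; returns a time-ordered list of (time_s, amp_mV).

    The envelope is the squared derivative of the 5–40 Hz band-passed
    signal, smoothed over 60 ms. The per-sample threshold is
    ``k x rolling median`` of the envelope (1 s blocks) with a floor at 10%
    of the envelope maximum. Each suprathreshold envelope peak is refined
    to the raw-signal maximum within +/- 25 ms; peaks closer than the
    running refractory period keep the larger amplitude.
    """
    _check_signal(trace)
    fs = trace.fs
    v = np.nan_to_num(trace.voltage)

    band = _bandpass(v, fs, params.r_band_hz)
    env = np.gradient(band) * fs
    env = env * env
    smooth_w = max(1, int(round(0.06 * fs)))
    env = np.convolve(env, np.ones(smooth_w) / smooth_w, mode="same")

    thr = params.r_threshold_k * _block_stat(env, fs, 1.0, np.median)
    thr = np.maximum(thr, 0.1 * env.max())

    dist = max(1, int(round(params.r_refractory_init_s * fs)))
    cand, _ = signal.find_peaks(env, distance=dist)
    cand = cand[env[cand] >= thr[cand]]
    if cand.size == 0:
        return []

    half = int(round(0.025 * fs))
    flat = _detrended(v, fs)
    accepted: list[tuple[int, float]] = []  # (raw index, amplitude)
    recent_ibis: list[float] = []
    est_ibi = params.r_refractory_init_s / params.r_refractory_frac
    for c in cand:
        lo, hi = max(0, c - half), min(v.size, c + half + 1)
        r_idx = lo + int(np.argmax(flat[lo:hi]))
        base = _local_baseline(flat, fs, r_idx, params.baseline_window_s)
        amp = float(flat[r_idx] - base)
        if accepted:
            refractory = params.r_refractory_frac * est_ibi
            gap = (r_idx - accepted[-1][0]) / fs
            if gap < refractory:
                if amp > accepted[-1][1]:
                    accepted[-1] = (r_idx, amp)  # replace with larger peak
                continue
            # only typical cycles update the running interbeat estimate;
            # sinus-arrest pauses would otherwise inflate the refractory
            # until it swallowed genuine beats
            if gap < 1.5 * est_ibi:
                recent_ibis.append(gap)
                est_ibi = float(np.median(recent_ibis[-8:]))
        accepted.append((r_idx, amp))

    return [(idx / fs, amp) for idx, amp in accepted]


def detect_p_waves(
    trace: ECGTrace,
    r_peaks: Optional[Sequence[tuple[float, float]]] = None,
    params: DetectorParams = DetectorParams(),
) -> list[tuple[float, float]]:
    """Detect P waves; returns a time-ordered list of (time_s, amp_mV).

    With ``r_peaks`` given, the P wave is the most prominent positive peak
    on the 1–30 Hz signal inside ``[r - 0.15 s, r - 0.02 s]``; windows
    crossing the trace boundary are skipped. Standalone mode (no usable
    QRS) picks peaks by prominence (k_p x rolling MAD, 2 s blocks) with a
    0.3 s refractory, then prunes candidates whose filtered height falls
    below 35% of the candidate median — bandlimited noise bumps inside long
    pauses survive a pure prominence rule and would split those pauses.
    """
    fs = trace.fs
    v = np.nan_to_num(trace.voltage)
    if r_peaks is None and np.ptp(v[np.isfinite(v)] if np.isfinite(v).any() else v) == 0.0:
        return []  # nothing to pick on a flat trace
    _check_signal(trace)
    low = _bandpass(v, fs, params.p_band_hz)
    flat = _detrended(v, fs)
    # refinement signal: detrended and lightly smoothed — the band-passed
    # signal carries QRS ringing that tilts the P peak by a sample or two,
    # while the raw detrended signal jitters under wideband noise
    w = max(1, int(round(0.007 * fs)))
    smooth = np.convolve(flat, np.ones(w) / w, mode="same")
    refine = max(1, int(round(0.005 * fs)))

    def refine_idx(p_idx: int) -> int:
        lo = max(0, p_idx - refine)
        hi = min(smooth.size, p_idx + refine + 1)
        return lo + int(np.argmax(smooth[lo:hi]))

    def amp_at(p_idx: int) -> float:
        base = _local_baseline(flat, fs, p_idx, (0.07, 0.02))
        return float(flat[p_idx] - base)

    if r_peaks is not None:
        out: list[tuple[float, float]] = []
        w0 = int(round(params.p_window_s[0] * fs))
        w1 = int(round(params.p_window_s[1] * fs))
        for r_time, _ in r_peaks:
            r_idx = int(round(r_time * fs))
            lo, hi = r_idx - w0, r_idx - w1
            if lo < 0 or hi > low.size or hi - lo < 3:
                continue  # boundary windows are skipped, not errored
            seg = low[lo:hi]
            peaks, props = signal.find_peaks(seg, prominence=1e-12)
            if peaks.size == 0:
                continue
            best = peaks[int(np.argmax(props["prominences"]))]
            p_idx = refine_idx(lo + int(best))
            amp = amp_at(p_idx)
            if amp <= 0:  # positive-deflection requirement
                continue
            out.append((p_idx / fs, amp))
        return out

    # standalone mode
    mad_local = _block_stat(np.abs(low - np.median(low)), fs, 2.0, np.median)
    mad_global = float(np.median(np.abs(low - np.median(low))))
    dist = max(1, int(round(params.p_refractory_s * fs)))
    peaks, _ = signal.find_peaks(
        low, distance=dist, prominence=max(params.p_threshold_k * mad_global, 1e-12)
    )
    # enforce the local (rolling) MAD rule via height against the block MAD
    peaks = peaks[low[peaks] >= params.p_threshold_k * mad_local[peaks]]
    if peaks.size == 0:
        return []
    heights = low[peaks]
    med_h = float(np.median(heights))
    keep = heights >= params.p_height_prune_frac * med_h
    peaks = peaks[keep]
    refined = [refine_idx(int(p)) for p in peaks]
    return [(p / fs, amp_at(p)) for p in refined]


def delineate_qrs(
    trace: ECGTrace,
    r_peaks: Sequence[tuple[float, float]],
    params: DetectorParams = DetectorParams(),
) -> list[tuple[Optional[float], Optional[float], bool]]:
    """Delineate QRS on/offsets around each R peak.

    Returns one ``(onset_s, offset_s, ok)`` per R peak. Walking outward
    from R, the on/offset is the first sample where ``|v - baseline|``
    stays below 10% of ``|R - baseline|`` for at least 4 ms; beats where
    the search collapses (no sustained sub-threshold stretch within
    0.15 s) are flagged ``ok=False`` and must be excluded from
    duration averages.
    """
    if len(r_peaks) == 0:
        raise InsufficientDataError("delineation requires at least one R peak")
    fs = trace.fs
    v = _detrended(np.nan_to_num(trace.voltage), fs)
    sustain = max(1, int(round(params.qrs_sustain_s * fs)))
    reach = int(round(params.qrs_search_s * fs))

    out: list[tuple[Optional[float], Optional[float], bool]] = []
    for r_time, _ in r_peaks:
        r_idx = int(round(r_time * fs))
        base = _local_baseline(v, fs, r_idx, params.baseline_window_s)
        ref = abs(v[r_idx] - base)
        thr = params.qrs_threshold_frac * ref
        below = np.abs(v - base) < thr

        onset_idx: Optional[int] = None
        for i in range(r_idx - 1, max(0, r_idx - reach) - 1, -1):
            if i - sustain + 1 >= 0 and below[i - sustain + 1 : i + 1].all():
                onset_idx = i
                break
        offset_idx: Optional[int] = None
        for i in range(r_idx + 1, min(v.size, r_idx + reach)):
            if i + sustain <= v.size and below[i : i + sustain].all():
                offset_idx = i
                break
        ok = onset_idx is not None and offset_idx is not None
        if not ok:
            log.warning("QRS delineation collapsed for R at %.3f s", r_time)
            out.append((None, None, False))
        else:
            out.append((onset_idx / fs, offset_idx / fs, True))
    return out


def assemble_beats(
    p_list: Sequence[tuple[float, float]],
    r_list: Optional[Sequence[tuple[float, float]]],
    qrs_list: Optional[Sequence[tuple[Optional[float], Optional[float], bool]]],
    trace: ECGTrace,
    pair_window_s: tuple[float, float] = (0.01, 0.2),
) -> BeatSet:
    """Assemble P, R and QRS streams into a BeatSet.

    A P and an R pair when ``r - p`` lies in ``pair_window_s`` (each P takes
    the nearest following R at most once). Unpaired P waves become beats
    with ``qrs_detected=False``; unpaired R peaks are logged and dropped —
    the atrial stream defines the beat list.
    """
    r_list = list(r_list) if r_list else []
    qrs_list = list(qrs_list) if qrs_list else [(None, None, False)] * len(r_list)
    used_r = [False] * len(r_list)

    beats: list[Beat] = []
    last_p = -np.inf
    for p_time, p_amp in sorted(p_list):
        if p_time <= last_p:
            continue
        last_p = p_time
        match = None
        for j, (r_time, r_amp) in enumerate(r_list):
            if used_r[j]:
                continue
            dt = r_time - p_time
            if pair_window_s[0] < dt < pair_window_s[1]:
                match = j
                break
            if dt >= pair_window_s[1]:
                break
        if match is None:
            beats.append(Beat(p_time_s=p_time, p_amp_mV=p_amp))
        else:
            used_r[match] = True
            r_time, r_amp = r_list[match]
            onset, offset, ok = qrs_list[match]
            if ok and onset is not None and onset > p_time and offset > r_time:
                beats.append(Beat(
                    p_time_s=p_time, p_amp_mV=p_amp,
                    qrs_onset_s=onset, r_time_s=r_time,
                    r_amp_mV=r_amp, qrs_offset_s=offset, qrs_detected=True,
                ))
            else:
                # paired but not delineated: keep the R measurement, leave
                # duration-dependent fields empty by flagging undetected
                beats.append(Beat(p_time_s=p_time, p_amp_mV=p_amp))

    n_dropped = used_r.count(False)
    if n_dropped:
        log.warning("%d unpaired R peak(s) dropped", n_dropped)
    return BeatSet(beats=beats, trace_duration_s=trace.duration_s)


def estimate_noise_floor(trace: ECGTrace, beat_times_s: Sequence[float],
                         exclude_s: tuple[float, float] = (0.06, 0.30)) -> float:
    """Noise floor (mV) as the MAD of the band-passed trace outside beats.

    Samples within ``[p - 0.06 s, p + 0.30 s]`` of each detected beat are
    excluded so P/QRS/T deflections do not inflate the estimate; baseline
    wander is removed with a 1 Hz high-pass before taking the MAD.
    """
    fs = trace.fs
    v = np.nan_to_num(trace.voltage)
    nyq = fs / 2.0
    sos = signal.butter(2, 1.0 / nyq, btype="high", output="sos")
    flat = signal.sosfiltfilt(sos, v)
    mask = np.ones(flat.size, dtype=bool)
    for p in beat_times_s:
        lo = max(0, int((p - exclude_s[0]) * fs))
        hi = min(flat.size, int((p + exclude_s[1]) * fs))
        mask[lo:hi] = False
    resid = flat[mask] if mask.any() else flat
    return float(np.median(np.abs(resid - np.median(resid))))
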