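"""Plain-text readers/writers: trace CSV + JSON sidecar, beats CSV.

Trace files are two-column CSV (``time_s,voltage_mV``) with an optional
JSON metadata sidecar (``<stem>.meta.json``) carrying subject id, group,
sampling rate and a config echo. Beat tables are CSV with empty fields
where the QRS is missing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import Beat, BeatSet, ECGTrace
from .errors import ConfigError

__all__ = [
    "write_trace",
    "read_trace",
    "write_beats",
    "read_beats",
]

BEAT_COLUMNS = [
    "beat_idx", "p_time_s", "p_amp_mV", "qrs_onset_s",
    "r_time_s", "r_amp_mV", "qrs_offset_s", "qrs_detected",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trace(trace: ECGTrace, path, config=None) -> Path:
    """Write trace CSV and metadata sidecar; returns the CSV path."""
    path = Path(path)
    t = np.arange(trace.n_samples) / trace.fs
    frame = pd.DataFrame({"time_s": t, "voltage_mV": trace.voltage})
    frame.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "subject_id": trace.subject_id,
        "group": trace.group,
        "fs": trace.fs,
        "n_samples": trace.n_samples,
    }
    if config is not None:
        meta["config"] = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_trace(path) -> ECGTrace:
    """Read a trace CSV (+sidecar when present) back into an ECGTrace."""
    path = Path(path)
    frame = pd.read_csv(path)
    if not {"time_s", "voltage_mV"} <= set(frame.columns):
        raise ConfigError(f"{path} lacks time_s/voltage_mV columns")
    t = frame["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ConfigError(f"{path} has fewer than 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        fs = float(meta.get("fs", fs))
    return ECGTrace(
        voltage=frame["voltage_mV"].to_numpy(dtype=float),
        fs=fs,
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "")),
    )


def write_beats(beats: BeatSet, path) -> Path:
    path = Path(path)
    rows = []
    for i, b in enumerate(beats.beats):
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
    pd.DataFrame(rows, columns=BEAT_COLUMNS).to_csv(path, index=False)
    return path


def read_beats(path, trace_duration_s: Optional[float] = None) -> BeatSet:
    frame = pd.read_csv(path)
    beats = []
    for _, row in frame.iterrows():
        detected = bool(row["qrs_detected"])
        beats.append(Beat(
            p_time_s=float(row["p_time_s"]),
            p_amp_mV=float(row["p_amp_mV"]),
            qrs_onset_s=None if pd.isna(row["qrs_onset_s"]) else float(row["qrs_onset_s"]),
            r_time_s=None if pd.isna(row["r_time_s"]) else float(row["r_time_s"]),
            r_amp_mV=None if pd.isna(row["r_amp_mV"]) else float(row["r_amp_mV"]),
            qrs_offset_s=None if pd.isna(row["qrs_offset_s"]) else float(row["qrs_offset_s"]),
            qrs_detected=detected,
        ))
    if trace_duration_s is None:
        trace_duration_s = beats[-1].p_time_s if beats else 0.0
    return BeatSet(beats=beats, trace_duration_s=trace_duration_s)
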