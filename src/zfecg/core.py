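"""Core data containers shared across the pipeline.

The analysis operates on a single-lead surface ECG sampled uniformly
(voltage in mV, time in seconds). Beats are anchored on the P wave — the
sinoatrial rhythm marker — because severely affected fish may lack a
distinguishable QRS complex, so every rhythm quantity must be computable
from the atrial stream alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError

__all__ = ["ECGTrace", "Beat", "BeatSet", "IntervalSeries"]


@dataclass
class ECGTrace:
    """Uniformly sampled single-lead voltage series.

    Parameters
    ----------
    voltage : ndarray
        Voltage in millivolts.
    fs : float
        Sampling rate in Hz.
    subject_id, group : str
        Free-text subject metadata carried through to reports.
    """

    voltage: np.ndarray
    fs: float
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.voltage.ndim != 1 or self.voltage.size < 2:
            raise ConfigError("trace must be a 1-D series with >= 2 samples")
        if not self.fs > 0:
            raise ConfigError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.voltage.size

    @property
    def duration_s(self) -> float:
        return self.voltage.size / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.voltage.size) / self.fs


@dataclass
class Beat:
    """Per-beat fiducials. QRS fields are None when no QRS was detected."""

    p_time_s: float
    p_amp_mV: float
    qrs_onset_s: Optional[float] = None
    r_time_s: Optional[float] = None
    r_amp_mV: Optional[float] = None
    qrs_offset_s: Optional[float] = None
    qrs_detected: bool = False

    def __post_init__(self) -> None:
        if self.qrs_detected:
            ts = (self.p_time_s, self.qrs_onset_s, self.r_time_s, self.qrs_offset_s)
            if any(t is None for t in ts[1:]):
                raise ConfigError("qrs_detected beat is missing QRS fiducials")


@dataclass
class BeatSet:
    """Ordered collection of beats from one recording."""

    beats: list[Beat]
    trace_duration_s: float

    def __post_init__(self) -> None:
        times = self.p_times_s
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ConfigError("beat P times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def p_times_s(self) -> np.ndarray:
        return np.array([b.p_time_s for b in self.beats], dtype=float)

    @property
    def p_amps_mV(self) -> np.ndarray:
        return np.array([b.p_amp_mV for b in self.beats], dtype=float)

    @property
    def qrs_fraction(self) -> float:
        """Fraction of beats with a detected QRS complex."""
        if not self.beats:
            return 0.0
        return sum(b.qrs_detected for b in self.beats) / len(self.beats)


@dataclass
class IntervalSeries:
    """Ordered P-P (interbeat) intervals of one recording, in seconds."""

    pp_s: np.ndarray
    recording_duration_min: float

    def __post_init__(self) -> None:
        self.pp_s = np.asarray(self.pp_s, dtype=float)
        if self.pp_s.size and np.any(self.pp_s <= 0):
            raise ConfigError("intervals must all be positive")
        if self.recording_duration_min < 0:
            raise ConfigError("recording duration must be non-negative")

    def __len__(self) -> int:
        return self.pp_s.size
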