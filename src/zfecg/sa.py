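"""Sinus-arrest (SA) episode scoring and cohort prevalence.

An SA episode is a P-P interval exceeding a definitive cutoff derived as a
fold change (default 2.5x) over the normal mean interbeat interval — for a
0.52 s wild-type mean this gives the 1.3 s cutoff used throughout. A
separate, lower screening cutoff (default 1.0 s) flags borderline-long
intervals for review; screened intervals do not enter prevalence.

Consecutively occurring episodes are counted as maximal runs of at least
two adjacent episode intervals (one run = one incidence); the alternative
unit — total member episodes inside such runs — is available via
``consecutive_unit="episodes"``. Each long interval counts as exactly one
episode regardless of its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import IntervalSeries
from .errors import ConfigError, InsufficientDataError

__all__ = [
    "SAReport",
    "derive_sa_cutoff",
    "detect_sa_episodes",
    "cohort_prevalence",
]


@dataclass
class SAReport:
    """SA scoring of one recording."""

    definitive_cutoff_s: float
    screening_cutoff_s: float
    episode_indices: list[int]
    screened_indices: list[int]
    n_episodes: int
    episodes_per_min: float
    n_consecutive_runs: int
    consecutive_runs_per_min: float
    has_sa: bool
    recording_duration_min: float

    def to_dict(self) -> dict:
        return {
            "definitive_cutoff_s": self.definitive_cutoff_s,
            "screening_cutoff_s": self.screening_cutoff_s,
            "episode_indices": list(map(int, self.episode_indices)),
            "screened_indices": list(map(int, self.screened_indices)),
            "n_episodes": self.n_episodes,
            "episodes_per_min": self.episodes_per_min,
            "n_consecutive_runs": self.n_consecutive_runs,
            "consecutive_runs_per_min": self.consecutive_runs_per_min,
            "has_sa": self.has_sa,
            "recording_duration_min": self.recording_duration_min,
        }


def derive_sa_cutoff(wt_mean_pp_s: float, fold: float = 2.5) -> float:
    """Definitive SA cutoff as a fold change over the normal mean interval."""
    if wt_mean_pp_s <= 0:
        raise ConfigError("mean P-P interval must be positive")
    if fold < 1.0:
        raise ConfigError("fold must be >= 1")
    return fold * wt_mean_pp_s


def _runs(indices: Sequence[int], unit: str) -> int:
    """Count consecutive-episode incidences among sorted interval indices."""
    idx = sorted(indices)
    runs = 0
    members = 0
    i = 0
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and idx[j + 1] == idx[j] + 1:
            j += 1
        if j > i:  # run of length >= 2
            runs += 1
            members += j - i + 1
        i = j + 1
    return members if unit == "episodes" else runs


def detect_sa_episodes(
    intervals: IntervalSeries,
    definitive_cutoff_s: float = 1.3,
    screening_cutoff_s: float = 1.0,
    consecutive_unit: str = "runs",
) -> SAReport:
    """Score one recording's interval series against the SA cutoffs."""
    if len(intervals) == 0:
        raise InsufficientDataError("interval series is empty")
    if definitive_cutoff_s < screening_cutoff_s:
        raise ConfigError("definitive cutoff must be >= screening cutoff")
    if consecutive_unit not in ("runs", "episodes"):
        raise ConfigError("consecutive_unit must be 'runs' or 'episodes'")
    dur = intervals.recording_duration_min
    if dur <= 0:
        raise ConfigError("recording duration must be positive")

    pp = intervals.pp_s
    episodes = np.flatnonzero(pp > definitive_cutoff_s)
    screened = np.flatnonzero(pp > screening_cutoff_s)
    n_runs = _runs(episodes.tolist(), consecutive_unit)

    return SAReport(
        definitive_cutoff_s=definitive_cutoff_s,
        screening_cutoff_s=screening_cutoff_s,
        episode_indices=episodes.tolist(),
        screened_indices=screened.tolist(),
        n_episodes=int(episodes.size),
        episodes_per_min=episodes.size / dur,
        n_consecutive_runs=n_runs,
        consecutive_runs_per_min=n_runs / dur,
        has_sa=bool(episodes.size >= 1),
        recording_duration_min=dur,
    )


def cohort_prevalence(
    reports: Sequence[tuple[str, SAReport, int]]
) -> pd.DataFrame:
    """Per-group SA prevalence and mean frequencies.

    ``reports`` is a sequence of (group label, SAReport, n beats analyzed).
    Per-minute frequencies are averaged per fish, then across fish within
    the group (not pooled episodes over pooled minutes). Returns one row
    per group, ordered by first appearance, with columns ``n_fish``,
    ``n_with_sa``, ``percent_with_sa``, ``mean_episodes_per_min``,
    ``mean_consecutive_runs_per_min``, ``total_beats``.
    """
    if not reports:
        raise InsufficientDataError("no reports supplied")
    order: list[str] = []
    groups: dict[str, list[tuple[SAReport, int]]] = {}
    for label, rep, n_beats in reports:
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append((rep, n_beats))

    rows = []
    for label in order:
        members = groups[label]
        if not members:
            raise InsufficientDataError(f"group {label!r} is empty")
        n = len(members)
        n_sa = sum(rep.has_sa for rep, _ in members)
        rows.append({
            "group": label,
            "n_fish": n,
            "n_with_sa": n_sa,
            "percent_with_sa": 100.0 * n_sa / n,
            "mean_episodes_per_min": float(np.mean([r.episodes_per_min for r, _ in members])),
            "mean_consecutive_runs_per_min": float(
                np.mean([r.consecutive_runs_per_min for r, _ in members])
            ),
            "total_beats": int(sum(nb for _, nb in members)),
        })
    return pd.DataFrame(rows).set_index("group")
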