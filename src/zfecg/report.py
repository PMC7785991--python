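"""Cohort report assembly: index tables, SA prevalence, group comparisons.

``build_cohort_report`` takes per-recording results and produces a
deterministic bundle: a per-metric group table (per-fish-then-group
averaging — group values are means of per-recording indices, never pooled
beats), the SA prevalence table, and unpaired t-test comparisons between a
reference group and each other group for every index with enough data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import sa as sa_mod
from .errors import InsufficientDataError, SubjectMismatchError
from .model import RhythmResults
from .stats import unpaired_t_test

__all__ = ["CohortReport", "build_cohort_report"]

_METRICS = [
    "hr_bpm", "mean_pp_s", "sd_pp_s", "mean_p_amp_mV",
    "mean_r_amp_mV", "p_over_r_ratio", "mean_pr_s", "mean_qrs_s",
]


@dataclass
class CohortReport:
    """Assembled cohort tables (deterministic given the same inputs)."""

    indices: pd.DataFrame        # one row per recording
    group_means: pd.DataFrame    # one row per group, mean/sd per metric
    sa_prevalence: pd.DataFrame  # per-group SA summary
    comparisons: pd.DataFrame    # reference-vs-group t-tests
    class_counts: pd.DataFrame   # ECG class tally per group

    def to_json(self) -> str:
        return json.dumps({
            "indices": self.indices.to_dict(orient="records"),
            "group_means": self.group_means.reset_index().to_dict(orient="records"),
            "sa_prevalence": self.sa_prevalence.reset_index().to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            "class_counts": self.class_counts.reset_index().to_dict(orient="records"),
        }, indent=1, sort_keys=True, default=float)

    def to_markdown(self) -> str:
        parts = [
            "# Cohort ECG report",
            "## Group means (per-fish averaging)",
            self.group_means.round(4).to_markdown(),
            "## Sinus-arrest prevalence",
            self.sa_prevalence.round(3).to_markdown(),
            "## Group comparisons (unpaired Student t)",
            self.comparisons.round(4).to_markdown(index=False),
            "## ECG class counts",
            self.class_counts.to_markdown(),
        ]
        return "\n\n".join(parts) + "\n"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        (out / "report.md").write_text(self.to_markdown())
        self.indices.to_csv(out / "indices.csv", index=False)
        self.sa_prevalence.to_csv(out / "sa_prevalence.csv")


def build_cohort_report(
    results: Sequence[tuple[str, str, RhythmResults]],
    reference_group: Optional[str] = None,
) -> CohortReport:
    """Assemble the cohort report from per-recording fit results.

    ``results`` is a sequence of (subject_id, group, RhythmResults).
    ``reference_group`` defaults to the first group seen; every other group
    is compared to it metric by metric.
    """
    if not results:
        raise InsufficientDataError("no per-recording results supplied")
    ids = [sid for sid, _, _ in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise SubjectMismatchError(f"duplicate subject ids: {dupes}")

    rows = []
    sa_rows = []
    for sid, group, res in sorted(results, key=lambda r: (r[1], r[0])):
        d = res.indices.to_dict()
        d.update({"subject_id": sid, "group": group, "n_beats": res.n_beats})
        rows.append(d)
        sa_rows.append((group, res.sa_report, res.n_beats))
    indices = pd.DataFrame(rows)
    indices = indices[["subject_id", "group", "n_beats"] +
                      _METRICS + ["qrs_detectability", "ecg_class"]]

    group_means = indices.groupby("group", sort=True)[_METRICS].agg(["mean", "std"])
    group_means.columns = [f"{metric}_{stat}" for metric, stat in group_means.columns]
    sa_prev = sa_mod.cohort_prevalence(sa_rows)

    ref = reference_group if reference_group is not None else indices["group"].iloc[0]
    if ref not in set(indices["group"]):
        raise SubjectMismatchError(f"reference group {ref!r} not present")
    comp_rows = []
    for group in sorted(set(indices["group"]) - {ref}):
        for metric in _METRICS:
            a = indices.loc[indices["group"] == ref, metric].dropna()
            b = indices.loc[indices["group"] == group, metric].dropna()
            if a.size < 2 or b.size < 2:
                continue
            try:
                c = unpaired_t_test(a, b, ref, group, metric)
            except Exception:
                continue
            comp_rows.append({
                "metric": metric, "group_a": ref, "group_b": group,
                "mean_a": c.mean_a, "mean_b": c.mean_b,
                "n_a": c.n_a, "n_b": c.n_b,
                "t": c.t_statistic, "p_value": c.p_value,
            })
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["metric", "group_a", "group_b", "mean_a", "mean_b",
                 "n_a", "n_b", "t", "p_value"],
    )

    class_counts = (
        indices.groupby(["group", "ecg_class"]).size().unstack(fill_value=0)
    )
    return CohortReport(
        indices=indices,
        group_means=group_means,
        sa_prevalence=sa_prev,
        comparisons=comparisons,
        class_counts=class_counts,
    )
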