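"""Group-comparison statistics and small closed-form laboratory formulas.

Group means are compared with the classical unpaired Student t-test
(pooled variance, df = n_a + n_b - 2); Welch's unequal-variance variant is
available behind a flag. No multiple-testing correction is applied to the
index panel. Also here: relative qPCR expression by the 2^(-ddCt) method,
baseline-normalized fluorescence (dF/F0), and the ventricular-to-atrial
surface-area ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    ConfigError,
    DegenerateVarianceError,
    InsufficientDataError,
    MissingConditionError,
)

__all__ = [
    "GroupComparison",
    "QPCRSample",
    "unpaired_t_test",
    "relative_expression",
    "delta_f_over_f",
    "chamber_area_ratio",
]


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    metric: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float


def unpaired_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    group_a: str = "A",
    group_b: str = "B",
    metric: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test on independent groups (Student by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            # identical constant samples: no evidence of difference
            return GroupComparison(group_a, group_b, metric,
                                   float(np.mean(a)), float(np.mean(b)),
                                   0.0, 0.0, a.size, b.size, 0.0, 1.0)
        raise DegenerateVarianceError(
            "both samples are constant; the t statistic is undefined"
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_a=group_a, group_b=group_b, metric=metric,
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)), sd_b=float(np.std(b, ddof=1)),
        n_a=int(a.size), n_b=int(b.size),
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class QPCRSample:
    """One qPCR well: target and reference cycle thresholds, condition label."""

    ct_target: float
    ct_reference: float
    condition: str  # "control" or "treatment"

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (np.isfinite(v) and v > 0):
                raise ConfigError("Ct values must be positive and finite")
        if self.condition not in ("control", "treatment"):
            raise ConfigError("condition must be 'control' or 'treatment'")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_expression(samples: Sequence[QPCRSample]) -> tuple[float, float]:
    """Relative expression by the 2^(-ddCt) method.

    Returns ``(fold, percent_reduction)`` where
    ddCt = mean dCt(treatment) - mean dCt(control), fold = 2^(-ddCt), and
    percent_reduction = 100 x (1 - fold) (negative when expression rises).
    """
    ctrl = [s.delta_ct for s in samples if s.condition == "control"]
    trt = [s.delta_ct for s in samples if s.condition == "treatment"]
    if not ctrl or not trt:
        raise MissingConditionError("need >= 1 sample per condition")
    ddct = float(np.mean(trt) - np.mean(ctrl))
    fold = float(2.0 ** (-ddct))
    return fold, 100.0 * (1.0 - fold)


def delta_f_over_f(f: Sequence[float], f0: float) -> np.ndarray:
    """Baseline-normalized fluorescence change (F - F0) / F0."""
    if not f0 > 0:
        raise ConfigError("baseline fluorescence must be positive")
    return (np.asarray(f, dtype=float) - f0) / f0


def chamber_area_ratio(vsa: float, asa: float) -> float:
    """Ventricular-to-atrial surface-area ratio VSA / ASA."""
    if vsa <= 0 or asa <= 0:
        raise ConfigError("surface areas must be positive")
    return vsa / asa
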