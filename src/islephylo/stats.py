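"""Percent-change summaries and the univariate contrasts of the analysis.

All contrasts are classical t-tests from :mod:`scipy.stats` with two-tailed
p-values: a one-sample t of per-island values against μ = 0, and a paired t
between the two periods (equivalent to a one-sample t on the differences).
Summaries are reported as mean ± SE (standard error, not SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "ChangeSummary",
    "percent_change",
    "one_sample_t",
    "paired_t",
    "change_summary",
]


@dataclass(frozen=True)
class TTestResult:
    """t statistic, two-tailed p and df; degenerate when sd = 0."""

    t: float | None
    p: float | None
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class ChangeSummary:
    """Per-island percent changes between periods with the μ = 0 contrast."""

    per_island_percent: list[tuple[str, float]]
    mean: float
    se: float
    t: float | None
    p: float | None
    df: int
    degenerate: bool = False

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.per_island_percent]


def percent_change(before: float, after: float) -> float:
    """100 · (after − before) / before; requires before > 0."""
    if before <= 0:
        raise ValueError(f"percent_change: 'before' must be positive, got {before}")
    return 100.0 * (after - before) / before


def one_sample_t(values: Sequence[float], mu: float = 0.0) -> TTestResult:
    """Classical one-sample t-test against ``mu`` (two-tailed)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("one_sample_t requires n >= 2")
    df = len(v) - 1
    if v.std(ddof=1) == 0:
        return TTestResult(None, None, df, degenerate=True)
    res = sps.ttest_1samp(v, popmean=mu)
    return TTestResult(float(res.statistic), float(res.pvalue), df)


def paired_t(before: Sequence[float], after: Sequence[float]) -> TTestResult:
    """Paired t-test between periods (one-sample t on the differences)."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("paired_t: unequal lengths")
    if len(b) < 2:
        raise ValueError("paired_t requires n >= 2")
    return one_sample_t(a - b, mu=0.0)


def change_summary(
    islands: Sequence[str],
    before: Sequence[float],
    after: Sequence[float],
) -> ChangeSummary:
    """Percent change per island plus the one-sample contrast against 0."""
    if not (len(islands) == len(before) == len(after)):
        raise ValueError("islands, before and after must have equal lengths")
    per = [
        (name, percent_change(b, a)) for name, b, a in zip(islands, before, after)
    ]
    v = np.asarray([x for _, x in per])
    mean = float(v.mean())
    se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
    if len(v) > 1 and v.std(ddof=1) > 0:
        tt = one_sample_t(v, mu=0.0)
    else:
        tt = TTestResult(None, None, max(len(v) - 1, 0), degenerate=True)
    return ChangeSummary(per, mean, se, tt.t, tt.p, tt.df, tt.degenerate)
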