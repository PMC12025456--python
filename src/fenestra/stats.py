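"""Group statistics: unpaired t-tests with star annotation and the
mean / sd / 5–95% percentile summaries used for box charts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TTestResult", "GroupSummary", "compare_groups", "summarize_group"]

DEFAULT_ALPHA_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    stars: str
    df: float
    welch: bool = False


@dataclass
class GroupSummary:
    """Box-chart summary: mean line, sd box, 5/95% whiskers (percentiles
    by linear interpolation between order statistics)."""

    label: str
    n: int
    mean: float
    sd: float
    percentile_5: float
    percentile_95: float
    sd_flagged: bool = False
    percentile_convention: str = "linear interpolation"


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS,
    welch: bool = False,
) -> TTestResult:
    """Two-sample unpaired t-test (equal-variance Student by default,
    Welch behind a flag) with star annotation at the alpha levels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = float(a.size + b.size - 2)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # zero pooled variance: identical constants agree perfectly,
        # different constants separate perfectly
        if a[0] == b[0]:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(a[0] - b[0]) * np.inf), 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
        if np.isnan(t):
            t, p = 0.0, 1.0
    stars = "".join("*" for lvl in sorted(alpha_levels, reverse=True) if p < lvl)
    return TTestResult(t_statistic=t, p_value=p, stars=stars, df=df, welch=welch)


def summarize_group(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean, sd and 5th/95th percentiles of one group (n >= 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    flagged = v.size == 1
    if flagged:
        warnings.warn("single observation: sd reported as 0")
        sd = 0.0
    else:
        sd = float(v.std(ddof=1))
    p5, p95 = np.percentile(v, [5, 95], method="linear")
    return GroupSummary(
        label=label,
        n=int(v.size),
        mean=float(v.mean()),
        sd=sd,
        percentile_5=float(p5),
        percentile_95=float(p95),
        sd_flagged=flagged,
    )
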