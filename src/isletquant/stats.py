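"""Two-group comparisons with an F-test-gated Welch correction.

The comparison rule: Student's t-test for two independent groups, but with
Welch's correction applied when an F test finds the group variances
significantly different (two-sided, alpha 0.05); a paired t-test when all
values are paired between the groups.  Also provides the coefficient of
variation used for size-uniformity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_two_groups", "coefficient_of_variation"]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    test_used: Literal["student", "welch", "paired"]
    f_statistic: float
    f_pvalue: float
    t_statistic: float
    t_pvalue: float
    significant: bool


def _variance_f_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Two-sided F test: larger sample variance in the numerator, p doubled.
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx >= vy:
        f, dfn, dfd = (vx / vy if vy > 0 else np.inf), len(x) - 1, len(y) - 1
    else:
        f, dfn, dfd = vy / vx, len(y) - 1, len(x) - 1
    p = min(1.0, 2.0 * sps.f.sf(f, dfn, dfd))
    return float(f), float(p)


def compare_two_groups(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare two groups of measurements; two-sided p-values throughout.

    Paired data get a paired t-test.  Otherwise an F test on the sample
    variances gates the choice: variances significantly different
    (p < alpha) selects Welch's unequal-variance t-test, else the pooled
    Student t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two values per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison requires equal-length groups")
        diff = x - y
        if np.all(diff == 0):
            # degenerate: identical pairs — no evidence of any difference
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x, y)
        return ComparisonResult(
            test_used="paired",
            f_statistic=float("nan"),
            f_pvalue=float("nan"),
            t_statistic=float(t),
            t_pvalue=float(p),
            significant=bool(p < alpha),
        )
    f_stat, f_p = _variance_f_test(x, y)
    use_welch = f_p < alpha
    t, p = sps.ttest_ind(x, y, equal_var=not use_welch)
    return ComparisonResult(
        test_used="welch" if use_welch else "student",
        f_statistic=f_stat,
        f_pvalue=f_p,
        t_statistic=float(t),
        t_pvalue=float(p),
        significant=bool(p < alpha),
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV% = 100 * sample SD (n-1) / mean; requires n >= 2 and mean > 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)
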