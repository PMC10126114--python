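"""Statistical-comparison plumbing with a normality-gated test choice.

Two-sample comparisons use the Shapiro-Wilk test on each sample: when both
pass (p > alpha) a two-sample t test (or one-way ANOVA for > 2 groups) is
used, otherwise the Mann-Whitney U (or Kruskal-Wallis) test.  Effect sizes
are pooled-SD Cohen's d with |d| > 0.8 flagged as large.  Multiple
comparisons are Holm-Bonferroni corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .phaselock import holm_bonferroni  # noqa: F401  (re-exported utility)

__all__ = ["CompareResult", "cohen_d", "compare_two", "compare_groups", "holm_bonferroni"]

LARGE_EFFECT = 0.8


def cohen_d(x, y) -> float:
    """Cohen's d with pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    sp = math.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if sp == 0:
        return 0.0 if x.mean() == y.mean() else math.inf
    return float((x.mean() - y.mean()) / sp)


@dataclass
class CompareResult:
    test: str
    statistic: float
    pvalue: float
    effect_size: float = math.nan
    large_effect: bool = False


def _is_normal(x, alpha: float) -> bool:
    if len(x) < 3:
        return False
    return sstats.shapiro(x).pvalue > alpha


def compare_two(x, y, alpha_normal: float = 0.05) -> CompareResult:
    """Two-sample comparison, parametric when both samples look normal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = cohen_d(x, y)
    if _is_normal(x, alpha_normal) and _is_normal(y, alpha_normal):
        res = sstats.ttest_ind(x, y)
        name = "t-test"
    else:
        res = sstats.mannwhitneyu(x, y)
        name = "mann-whitney"
    return CompareResult(
        test=name,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        effect_size=d,
        large_effect=abs(d) > LARGE_EFFECT,
    )


def compare_groups(*samples, alpha_normal: float = 0.05) -> CompareResult:
    """ANOVA across groups when all look normal, Kruskal-Wallis otherwise."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if all(_is_normal(np.asarray(s, dtype=float), alpha_normal) for s in samples):
        res = sstats.f_oneway(*samples)
        name = "anova"
    else:
        res = sstats.kruskal(*samples)
        name = "kruskal-wallis"
    return CompareResult(test=name, statistic=float(res.statistic), pvalue=float(res.pvalue))
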