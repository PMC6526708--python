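"""Condition comparisons with the normality-gated test-selection flow.

Each comparison first checks per-group normality (one-sample
Kolmogorov–Smirnov against a normal with the sample's mean and s.d. — a
Lilliefors-style screen, so the nominal KS p-values are approximate) and
equality of variances (F-test on the variance ratio).  Test choice:

* unpaired designs → Mann–Whitney U (the default rank test);
* paired designs with both groups normal → paired t-test;
* paired designs otherwise → Wilcoxon matched-pair signed-rank test.

The variance flag is recorded for the report but does not alter the choice.
Significance codes follow the usual convention: ns (p > 0.05), * (p < 0.05),
** (p < 0.01), *** (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats


@dataclass
class GroupComparison:
    design: str  # "paired" | "unpaired"
    test_used: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    normality_flags: tuple[bool, bool]
    equal_variance_flag: bool
    significance_code: str
    degenerate: bool = False
    paired_t: Optional[tuple[float, float]] = None  # (statistic, p) when paired
    wilcoxon: Optional[tuple[float, float]] = None  # (statistic, p) when paired

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BoxSummary:
    """Median, quartiles and full-range whiskers of one sample."""

    median: float
    q1: float
    q3: float
    min: float
    max: float
    n: int


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _ks_normal(sample: np.ndarray, alpha: float) -> bool:
    """True when KS (vs fitted normal) does not reject normality."""
    sd = sample.std(ddof=1)
    if sd == 0:
        return False
    _, p = stats.kstest(sample, "norm", args=(sample.mean(), sd))
    return p > alpha


def _f_test_equal_var(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        return va == vb
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    # two-sided p from the variance-ratio distribution
    p = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return p > alpha


def compare_groups(
    a, b, design: str = "unpaired", alpha: float = 0.05
) -> GroupComparison:
    """Compare two samples with the normality-gated decision flow.

    ``design`` is ``"paired"`` (equal-length, matched observations) or
    ``"unpaired"``.  For paired data both the paired t and Wilcoxon results
    are kept in the record regardless of which one fired.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if design not in ("paired", "unpaired"):
        raise ValueError(f"design must be 'paired' or 'unpaired', got {design!r}")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n ≥ 3 per group")
    if design == "paired" and len(a) != len(b):
        raise ValueError("paired design requires equal group sizes")

    normal_a = _ks_normal(a, alpha)
    normal_b = _ks_normal(b, alpha)
    equal_var = _f_test_equal_var(a, b, alpha)

    paired_t = wilcoxon_res = None
    degenerate = False
    if design == "paired":
        diffs = b - a
        if np.all(diffs == 0):
            # all matched differences zero: no evidence of any shift
            degenerate = True
            test_used, statistic, p = "wilcoxon", 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_rel(a, b)
            w_stat, w_p = stats.wilcoxon(a, b)
            paired_t = (float(t_stat), float(t_p))
            wilcoxon_res = (float(w_stat), float(w_p))
            if normal_a and normal_b:
                test_used, statistic, p = "paired_t", float(t_stat), float(t_p)
            else:
                test_used, statistic, p = "wilcoxon", float(w_stat), float(w_p)
    else:
        u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test_used, statistic, p = "mann_whitney_u", float(u_stat), float(u_p)

    return GroupComparison(
        design=design,
        test_used=test_used,
        statistic=statistic,
        p_value=float(p),
        n_per_group=(len(a), len(b)),
        normality_flags=(normal_a, normal_b),
        equal_variance_flag=equal_var,
        significance_code=significance_code(float(p)),
        degenerate=degenerate,
        paired_t=paired_t,
        wilcoxon=wilcoxon_res,
    )


def box_summary(sample) -> BoxSummary:
    """Median, linear-interpolation quartiles, and min/max whiskers."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("sample is empty")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return BoxSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        min=float(x.min()), max=float(x.max()), n=int(x.size),
    )
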