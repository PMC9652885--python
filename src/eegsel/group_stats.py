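"""Group-comparison statistics: chi-square for sex composition, pooled
two-tailed t-test for demographics (from raw values or printed summaries),
one-sample Kolmogorov-Smirnov normality gate, and Bonferroni-corrected
Wilcoxon signed-rank tests for paired accuracy comparisons."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

Summary = Tuple[float, float, int]  # (mean, sd, n)


@dataclass(frozen=True)
class ComparisonReport:
    """Result of one statistical comparison with Bonferroni correction."""

    test: str
    statistic: float
    p_raw: float
    m: int
    p_corrected: float
    stars: str

    @staticmethod
    def from_raw(test: str, statistic: float, p_raw: float, m: int
                 ) -> "ComparisonReport":
        if m < 1:
            raise ValueError("correction factor m must be >= 1")
        p_corr = min(1.0, m * p_raw)
        return ComparisonReport(test=test, statistic=float(statistic),
                                p_raw=float(p_raw), m=m,
                                p_corrected=float(p_corr),
                                stars=significance_stars(p_corr))


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.001, *** p<0.0001."""
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def chi_square_2x2(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, no continuity
    correction."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def _as_summary(x: Union[Summary, Sequence[float]]) -> Summary:
    if (isinstance(x, tuple) and len(x) == 3
            and np.isscalar(x[0]) and np.isscalar(x[1])):
        mean, sd, n = x
        return float(mean), float(sd), int(n)
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 observations per group")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def students_t_two_tailed(
    a: Union[Summary, Sequence[float]], b: Union[Summary, Sequence[float]]
) -> Tuple[float, float]:
    """Pooled-variance two-tailed Student's t-test; accepts raw vectors or
    (mean, sd, n) summaries interchangeably."""
    m1, s1, n1 = _as_summary(a)
    m2, s2, n2 = _as_summary(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if s1 == 0 and s2 == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(t), float(p)


def ks_normality(x: Sequence[float]) -> Tuple[float, float]:
    """One-sample KS test of the standardized sample against N(0, 1).

    Used only as a gate between the t-test and the signed-rank test.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 5:
        raise ValueError("need at least 5 observations")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input")
    z = (arr - arr.mean()) / sd
    stat, p = stats.kstest(z, "norm")
    return float(stat), float(p)


def wilcoxon_bonferroni(
    acc_a: Sequence[float], acc_b: Sequence[float], m: int = 20,
    test_name: Optional[str] = None,
) -> ComparisonReport:
    """Two-sided Wilcoxon signed-rank test on paired per-fold accuracies,
    zeros dropped, with Bonferroni correction factor ``m``."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    name = test_name or "wilcoxon_signed_rank"
    if np.all(diff == 0):
        return ComparisonReport.from_raw(name, 0.0, 1.0, m)
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return ComparisonReport.from_raw(name, stat, p, m)
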