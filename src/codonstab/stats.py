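"""Shared statistical routines for distribution comparisons.

Thin, documented wrappers around scipy's tests plus the variance-ratio
comparison of median-centered log2 half-life distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def ks_test(x, y) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    scipy's 'auto' switch point: exact p when n1*n2 <= 10000, asymptotic
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ks_2samp(x, y, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), len(x), len(y),
                      "two-sample KS")


def wilcoxon_test(x, y, paired: bool = False) -> TestResult:
    """Two-sided rank test: Wilcoxon signed-rank (paired) or Mann-Whitney U.

    Exact small-sample p-values where scipy's 'auto' mode provides them
    (signed-rank: n <= 25 without ties/zeros; Mann-Whitney: n <= 8 without
    ties), normal approximation with tie correction otherwise. Identical
    paired samples (all-zero differences) return statistic 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test requires equal-length samples")
        if np.all(x == y):
            return TestResult(0.0, 1.0, len(x), len(y),
                              "Wilcoxon signed-rank (degenerate: all-zero differences)")
        res = sps.wilcoxon(x, y, zero_method="wilcox", method="auto")
        return TestResult(float(res.statistic), float(res.pvalue), len(x), len(y),
                          "Wilcoxon signed-rank")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), len(x), len(y),
                      "Mann-Whitney U")


def median_center(x) -> np.ndarray:
    """x - median(x); for even length the median is the mean of the middle two
    order statistics (numpy convention), so the output median is exactly 0."""
    x = np.asarray(x, dtype=float)
    return x - np.median(x)


def variance_ratio(x_half_lives, y_half_lives, *, log2: bool = True) -> TestResult:
    """Variance ratio var(y)/var(x) of median-centered log2 half-lives.

    ``statistic`` is the ratio; the two-sided p-value comes from the F
    distribution with (n_y - 1, n_x - 1) degrees of freedom. Pass
    ``log2=False`` if the inputs are already on a log scale.
    """
    x = np.asarray(x_half_lives, dtype=float)
    y = np.asarray(y_half_lives, dtype=float)
    if log2:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("half-lives must be positive for the log2 scale")
        x, y = np.log2(x), np.log2(y)
    x = median_center(x)
    y = median_center(y)
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0:
        raise ValueError("zero variance in reference sample")
    ratio = vy / vx
    dist = sps.f(len(y) - 1, len(x) - 1)
    p = 2.0 * min(dist.cdf(ratio), dist.sf(ratio))
    return TestResult(ratio, min(float(p), 1.0), len(x), len(y),
                      "F test on median-centered log2 half-lives")
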