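"""Statistical primitives shared by every analysis stage.

All hypothesis tests are two-sided and return :class:`TestResult`; binomial
proportions are summarized with exact (Clopper-Pearson) intervals.  The
functions here are thin, validated wrappers around scipy/statsmodels with the
degenerate-input policy pinned down explicitly, because the pipeline routinely
feeds them edge cases (identical paired vectors, zero-variance differences)
that the underlying libraries handle with NaNs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ProportionCI",
    "ks_two_sample",
    "bh_fdr",
    "paired_t",
    "wilcoxon_rank_sum",
    "clopper_pearson",
    "response_summary",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample (or paired) hypothesis test.

    ``degenerate`` marks results where the test statistic is undefined in the
    usual sense (e.g. zero-variance paired differences) and the p-value was
    assigned by the documented limit rule rather than computed.
    """

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    two_sided: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with an exact two-sided confidence interval."""

    successes: int
    total: int
    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    percent: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.successes > self.total:
            raise ValueError("successes > total")
        if not (0.0 <= self.lower <= self.estimate <= self.upper <= 1.0):
            raise ValueError("CI bounds must satisfy 0 <= lower <= estimate <= upper <= 1")


def _as_finite_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum distance between the two empirical CDFs; the
    p-value uses the asymptotic Kolmogorov distribution, which is adequate at
    the sample sizes this pipeline produces (hundreds of mutations per
    sample).
    """
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    res = sps.ks_2samp(xa, ya, alternative="two-sided", method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n1=xa.size,
        n2=ya.size,
        method="ks_two_sample",
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returns q_i = min over j with p_(j) >= p_(i) of min(1, m * p_(j) / j),
    mapped back to input order.
    """
    pa = _as_finite_1d(p, "p")
    if np.any((pa < 0) | (pa > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(pa, method="fdr_bh")
    return q


def paired_t(pre, post) -> TestResult:
    """Two-sided paired t test on post - pre differences.

    Zero-variance differences are flagged degenerate instead of propagating
    NaN: all-zero differences give p = 1 (no evidence of change); constant
    nonzero differences give p = 0, the limit of the t test as the variance
    of a fixed nonzero shift goes to zero.
    """
    pre_a = _as_finite_1d(pre, "pre")
    post_a = _as_finite_1d(post, "post")
    if pre_a.size != post_a.size:
        raise ValueError("pre and post must have equal length (aligned pairs)")
    if pre_a.size < 2:
        raise ValueError("paired t requires at least 2 pairs")
    diff = post_a - pre_a
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return TestResult(0.0, 1.0, pre_a.size, post_a.size, "paired_t", degenerate=True)
        stat = math.inf if diff[0] > 0 else -math.inf
        return TestResult(stat, 0.0, pre_a.size, post_a.size, "paired_t", degenerate=True)
    res = sps.ttest_rel(post_a, pre_a)
    return TestResult(float(res.statistic), float(res.pvalue), pre_a.size, post_a.size, "paired_t")


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small samples without ties; normal
    approximation with tie correction otherwise.  The reported statistic is
    the rank sum of ``x`` (W = U + n1(n1+1)/2).
    """
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    small = xa.size + ya.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    rank_sum = float(res.statistic) + xa.size * (xa.size + 1) / 2.0
    return TestResult(
        statistic=rank_sum,
        p_value=float(min(1.0, res.pvalue)),
        n1=xa.size,
        n2=ya.size,
        method=f"wilcoxon_rank_sum_{method}",
    )


def clopper_pearson(successes: int, total: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial confidence interval from beta distribution quantiles."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    if successes == 0:
        lower = 0.0
    else:
        lower = float(sps.beta.ppf(alpha / 2.0, successes, total - successes + 1))
    if successes == total:
        upper = 1.0
    else:
        upper = float(sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, total - successes))
    return ProportionCI(
        successes=successes,
        total=total,
        estimate=successes / total,
        lower=lower,
        upper=upper,
        level=level,
    )


def response_summary(responders: int, enrolled: int, level: float = 0.95) -> ProportionCI:
    """Response-rate summary: whole-number percent plus exact CI.

    The percent is rounded half away from zero, so 8 of 21 reports as 38%.
    """
    if enrolled == 0:
        raise ValueError("enrolled must be >= 1")
    ci = clopper_pearson(responders, enrolled, level=level)
    percent = int(math.floor(100.0 * responders / enrolled + 0.5))
    return ProportionCI(
        successes=ci.successes,
        total=ci.total,
        estimate=ci.estimate,
        lower=ci.lower,
        upper=ci.upper,
        level=ci.level,
        percent=percent,
    )
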