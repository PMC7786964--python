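"""Shared statistical kernels with explicit small-sample contracts.

Every test here is two-sided.  Exact modes are used where enumeration is
cheap (Wilcoxon rank-sum at combined n <= 20, Fisher's exact throughout)
and each exact mode is checked against brute-force enumeration in the test
suite.  scipy provides the distributions; the exact Wilcoxon mode is an
in-package enumeration because midrank ties need to be handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "ks_two_sample",
    "fisher_exact_2x2",
    "chi_squared",
    "pearson",
    "bh_adjust",
]

WILCOXON_EXACT_MAX_N = 20  # combined sample size for exact enumeration


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    alternative: str = "two-sided"


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-tailed Wilcoxon (Mann-Whitney) rank-sum test.

    Midranks are used for ties.  For combined n <= 20 the p-value is exact:
    all C(n, n1) assignments of ranks to the first sample are enumerated and
    the two-sided p is the fraction of assignments whose rank-sum deviates
    from its null mean by at least as much as the observed one.  Larger
    samples use the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: empty input")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = st.rankdata(combined)
    w = float(ranks[:n1].sum())
    mu = n1 * ranks.mean()  # = n1*(n+1)/2 without ties, robust with midranks

    if n1 + n2 <= WILCOXON_EXACT_MAX_N:
        obs_dev = abs(w - mu)
        total = 0
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
        method = "Wilcoxon rank-sum (exact enumeration)"
    else:
        res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "Wilcoxon rank-sum (normal approximation)"
    return TestResult(statistic=w, p_value=min(p, 1.0), method=method)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample: empty input")
    res = st.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="two-sample Kolmogorov-Smirnov (asymptotic)",
    )


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test on a 2x2 table, conditional two-sided p.

    p sums the probabilities of all tables with the observed margins whose
    hypergeometric probability is <= the observed table's.  The statistic
    is the sample odds ratio ad/bc (inf when bc = 0).  A zero margin gives
    p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_2x2: need a non-negative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return TestResult(statistic=float(odds), p_value=1.0,
                          method="Fisher's exact test")
    _, p = st.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(min(p, 1.0)),
                      method="Fisher's exact test")


def chi_squared(table) -> TestResult:
    """Pearson chi-squared test of independence on an RxC table, no
    continuity correction; df = (R-1)(C-1)."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi_squared: zero row or column margin")
    res = st.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      method=f"chi-squared (df={res.dof})")


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t distribution
    (t = r sqrt((n-2)/(1-r^2)), n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson: need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson: zero-variance input")
    res = st.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
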