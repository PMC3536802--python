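"""Nonparametric and categorical hypothesis tests used throughout the
pipeline: Mann-Whitney U, Wilcoxon signed-rank, Kruskal-Wallis, and the
Pearson chi-square test.  All p-values are two-sided.

These wrap scipy.stats behind one result type, with documented switching
between exact null enumeration (small, tie-free samples) and the
tie-corrected normal / chi-square approximations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Largest group size for which Mann-Whitney uses exact enumeration (tie-free data).
MW_EXACT_LIMIT = 10
#: Largest number of non-zero pairs for which Wilcoxon uses exact enumeration.
WSR_EXACT_LIMIT = 20


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str  # exact | normal_approx | chisq_approx

    def as_record(self) -> dict:
        return {"test": self.test_name, "statistic": self.statistic,
                "p": self.p_value, "n": list(self.n), "method": self.method}


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (ties counted 1/2 in U).

    Exact enumeration of the null when both samples have at most
    ``MW_EXACT_LIMIT`` observations and the pooled data is tie-free;
    otherwise the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    exact = max(len(x), len(y)) <= MW_EXACT_LIMIT and not _has_ties(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      (len(x), len(y)), "exact" if exact else "normal_approx")


def _wsr_exact_p(d: np.ndarray) -> float:
    """Exact two-sided sign-flip p-value for the signed-rank statistic.

    Midranks handle tied |differences|; the null distribution of the
    (doubled, hence integer) positive-rank sum is built by generating-
    function convolution over all 2^n equally likely sign patterns.
    """
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)
    w2_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    mean2 = total / 2.0
    support = np.arange(total + 1)
    dev = abs(w2_obs - mean2)
    return float(dist[np.abs(support - mean2) >= dev - 1e-9].sum() / 2 ** len(d))


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's original convention).  Exact
    enumeration of the 2^n sign patterns when at most ``WSR_EXACT_LIMIT``
    non-zero pairs remain (tied |differences| handled by midranks);
    otherwise the tie-corrected, continuity-corrected normal approximation.
    The statistic is W, the sum of positive-difference ranks.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("pre and post must be paired (equal lengths)")
    d = pre - post
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, (len(pre),), "exact")
    if len(nz) < 5:
        warnings.warn(f"only {len(nz)} non-zero differences; test has little power")
    exact = len(nz) <= WSR_EXACT_LIMIT
    if exact:
        p = _wsr_exact_p(nz)
    else:
        p = float(stats.wilcoxon(nz, alternative="two-sided", method="asymptotic",
                                 correction=True).pvalue)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    return TestResult("wilcoxon_signed_rank", w_plus, min(p, 1.0),
                      (len(nz),), "exact" if exact else "normal_approx")


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test across three or more groups (tie-corrected),
    p from the chi-square approximation with k−1 degrees of freedom."""
    if len(groups) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups (use mann_whitney for 2)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if all(len(np.unique(a)) == 1 for a in arrays) and len(np.unique(np.concatenate(arrays))) == 1:
        return TestResult("kruskal_wallis", 0.0, 1.0,
                          tuple(len(a) for a in arrays), "chisq_approx")
    res = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(res.statistic), float(res.pvalue),
                      tuple(len(a) for a in arrays), "chisq_approx")


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Yates continuity correction is off by default (enable with ``yates``).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total; drop empty rows/columns first")
    res = stats.chi2_contingency(t, correction=yates)
    return TestResult("chi_square", float(res.statistic), float(res.pvalue),
                      (int(t.sum()),), "chisq_approx")


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted p-values and rejection flags.

    Provided as an extension; the pipeline's screening stages apply no
    multiple-testing correction by default.
    """
    p = np.asarray(p_values, dtype=float)
    adj = np.minimum(p * len(p), 1.0)
    return adj, adj < alpha
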