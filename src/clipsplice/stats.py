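"""Shared statistical primitives.

Exact small-sample paths (Mann-Whitney U, Spearman, paired sign-flip
permutation) are implemented by enumeration; large-sample paths and the
standard tests (Welch's t, Fisher's exact, Kruskal-Wallis, hypergeometric
tail) delegate to :mod:`scipy.stats`.

Two-sided convention throughout: P = 2 * min(lower tail, upper tail),
capped at 1.  For a 4-vs-4 complete separation this yields 2/70 = 0.0286,
and for 2-vs-3 complete separation 2/10 = 0.2000 -- the values exact rank
tests are expected to print for those designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_exact",
    "hypergeom_sf",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "pairwise_ranksum",
    "welch_t_log",
    "welch_t",
    "spearman",
    "sign_flip_test",
    "benjamini_hochberg",
]

# combined-n cutoff under which rank tests always take the exact path
EXACT_N_MAX = 12
# largest number of label assignments we are willing to enumerate
MAX_ENUM = 1_000_000


@dataclass(frozen=True)
class TestResult:
    """Statistic plus two-sided P and the method actually used."""

    statistic: float
    p_two_sided: float
    method: str
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _two_sided(p_low: float, p_high: float) -> float:
    return min(1.0, 2.0 * min(p_low, p_high))


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by enumeration when feasible.

    The exact path assigns midranks to the pooled sample and enumerates
    every :math:`\\binom{n_1+n_2}{n_1}` assignment of ranks to the first
    group, so ties are handled without approximation.  Larger designs fall
    back to the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    n_assign = math.comb(n, n1)
    ranks = _midranks(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    u_obs = w_obs - n1 * (n1 + 1) / 2.0

    if n <= EXACT_N_MAX or n_assign <= MAX_ENUM:
        # enumerate the rank-sum distribution over all label assignments
        lo = hi = 0
        for idx in itertools.combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            if w <= w_obs + 1e-9:
                lo += 1
            if w >= w_obs - 1e-9:
                hi += 1
        p = _two_sided(lo / n_assign, hi / n_assign)
        return TestResult(float(u_obs), p, "exact")

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "normal-approximation")


def hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric arguments N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Conditional two-sided Fisher's exact test with the sample odds ratio.

    The odds ratio is (a*d)/(b*c); a zero denominator is reported as
    ``inf`` with ``extra['or_infinite']`` set, and P is still computed.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("Fisher's exact test undefined for an all-zero margin")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    _, p = sps.fisher_exact(t, alternative="two-sided")
    if b * c == 0:
        odds, infinite = math.inf, True
    else:
        odds, infinite = (a * d) / (b * c), False
    return TestResult(odds, float(p), "exact", extra={"or_infinite": infinite})


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared P."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H = 0 by convention
        return TestResult(0.0, 1.0, "chi-squared")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "chi-squared")


def pairwise_ranksum(
    groups: Sequence[Sequence[float]], bonferroni: bool = False
) -> list[list[TestResult | None]]:
    """Matrix of two-sided rank-sum tests for every pair of groups.

    Uses the exact Mann-Whitney path for small designs.  No multiplicity
    adjustment by default; ``bonferroni=True`` multiplies each P by the
    number of pairs (capped at 1).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n_pairs = k * (k - 1) // 2
    out: list[list[TestResult | None]] = [[None] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            r = mann_whitney_exact(groups[i], groups[j])
            if bonferroni:
                r = TestResult(r.statistic, min(1.0, r.p_two_sided * n_pairs), r.method, r.extra)
            out[i][j] = out[j][i] = r
    return out


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch's t test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's test needs >= 2 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # zero variance in both groups: no evidence either way
        return TestResult(0.0, 1.0, "degenerate")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), "welch-t")


def welch_t_log(x: Sequence[float], y: Sequence[float], pseudocount: float = 1.0) -> TestResult:
    """Welch's t on log2(value + pseudocount), the proteomics-screen transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t(np.log2(x + pseudocount), np.log2(y + pseudocount))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation; exact permutation P for n <= 9."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("Spearman needs paired samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant sample")
    rho, p_approx = sps.spearmanr(x, y)
    n = x.size
    if n <= 9:
        rx = _midranks(x)
        ry = _midranks(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return TestResult(float(rho), count / total, "exact")
    return TestResult(float(rho), float(p_approx), "t-approximation")


def sign_flip_test(diffs: Sequence[float]) -> TestResult:
    """Exact two-sided paired test by enumerating all sign flips.

    The statistic is the mean of the paired differences; P is the fraction
    of the 2^n sign assignments whose |mean| is at least the observed one.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one paired difference")
    if d.size > 20:
        raise ValueError("sign-flip enumeration limited to 20 pairs")
    obs = abs(d.mean())
    signs = np.array(list(itertools.product([1.0, -1.0], repeat=d.size)))
    perm_means = np.abs(signs @ d) / d.size
    p = float(np.mean(perm_means >= obs - 1e-12))
    return TestResult(float(d.mean()), p, "exact")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Plain BH-adjusted q-values (used by the synthetic rMATS generator)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
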