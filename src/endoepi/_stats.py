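"""Shared statistical primitives.

Two conventions matter enough to pin down here:

* The two-sided Fisher exact p is computed by exact integer hypergeometric
  enumeration with the probability-mass tie criterion (sum the probabilities
  of all tables, with the observed margins, whose probability does not exceed
  the observed table's).  Integer arithmetic makes tie comparisons exact.
* Wilcoxon rank-sum tests use the exact null distribution when both samples
  have at most ten observations and carry no ties, and the normal
  approximation with tie correction otherwise.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats

EXACT_MAX_N = 10


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``.  The odds ratio is the sample odds ratio
    a*d / (b*c) (inf when b*c == 0 and a*d > 0, nan for the doubly degenerate
    table).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("contingency counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)

    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return odds, 1.0

    # support of the hypergeometric count in cell (1,1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    # unnormalised integer weights C(col1, k) * C(n - col1, row1 - k)
    weights = [comb(col1, k) * comb(n - col1, row1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    tail = sum(w for w in weights if w <= observed)
    p = float(Fraction(tail, comb(n, row1)))
    return odds, min(1.0, p)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
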