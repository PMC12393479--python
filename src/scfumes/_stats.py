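"""Shared statistical utilities.

Benjamini-Hochberg adjustment with NaN propagation, an exact rank-sum test
that handles ties through midranks, and enumeration/sampling of cell-label
assignments for permutation nulls.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fdr_adjust",
    "exact_ranksum_p",
    "count_label_assignments",
    "label_assignments",
]


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries are excluded from the ranking and propagated as NaN.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def count_label_assignments(labels) -> int:
    """Number of distinct orderings of a multiset of labels."""
    counts = Counter(np.asarray(labels).tolist())
    n = math.factorial(sum(counts.values()))
    for c in counts.values():
        n //= math.factorial(c)
    return n


def _distinct_permutations(codes: np.ndarray):
    """All distinct orderings of the integer multiset ``codes`` (lexicographic)."""
    counts = Counter(codes.tolist())
    keys = sorted(counts)
    n = len(codes)
    perm = np.empty(n, dtype=codes.dtype)
    out = []

    def rec(i: int) -> None:
        if i == n:
            out.append(perm.copy())
            return
        for k in keys:
            if counts[k]:
                counts[k] -= 1
                perm[i] = k
                rec(i + 1)
                counts[k] += 1

    rec(0)
    return out


def label_assignments(codes, n_perm: int, rng: np.random.Generator,
                      method: str = "auto"):
    """Label assignments for a permutation null.

    Returns ``(assignments, exhaustive)``. With ``method='exhaustive'``, or
    with ``method='auto'`` when the number of distinct orderings does not
    exceed ``n_perm``, every distinct ordering (including the identity) is
    returned once and ``exhaustive`` is True. Otherwise ``n_perm`` uniform
    random shuffles are drawn.
    """
    codes = np.asarray(codes)
    if method not in {"auto", "exhaustive", "sampling"}:
        raise ValueError(f"unknown method {method!r}")
    n_distinct = count_label_assignments(codes)
    if method == "exhaustive" or (method == "auto" and n_distinct <= n_perm):
        return _distinct_permutations(codes), True
    return [rng.permutation(codes) for _ in range(n_perm)], False


def exact_ranksum_p(x, y, max_combinations: int = 20_000) -> float:
    """Two-sided rank-sum p-value, exact by enumeration when feasible.

    The statistic is the Wilcoxon rank sum of ``x`` with midranks for ties;
    the two-sided p is the proportion of group assignments whose rank sum
    deviates from its null mean at least as much as observed (so identical
    samples give p = 1 exactly). Falls back to the tie-corrected normal
    approximation when C(n, n_x) exceeds ``max_combinations``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = n1 + n2
    expected = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    if math.comb(n, n1) <= max_combinations:
        dev_obs = abs(w_obs - expected)
        hits = total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - expected) >= dev_obs - 1e-12:
                hits += 1
        return hits / total
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
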