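"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive — plain Python loops, direct
enumeration — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_ranks(column):
    """Midranks of one pooled column."""
    column = list(column)
    out = []
    for v in column:
        less = sum(1 for u in column if u < v)
        equal = sum(1 for u in column if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def enumerate_exact_pvalue(column, n1):
    """Exact two-sided rank-sum p-value by enumerating all labellings."""
    n = len(column)
    ranks = naive_ranks(column)
    observed = sum(ranks[:n1])
    sums = [sum(ranks[i] for i in subset)
            for subset in itertools.combinations(range(n), n1)]
    lo = sum(1 for s in sums if s <= observed)
    hi = sum(1 for s in sums if s >= observed)
    total = len(sums)
    return min(1.0, 2.0 * min(lo, hi) / total)


def naive_bin_sum(pvals, lo, hi):
    """-2 sum(ln p) over the half-open bin [lo, hi)."""
    total = 0.0
    count = 0
    for p in pvals:
        if lo <= p < hi:
            total += -2.0 * math.log(p)
            count += 1
    return total, count


def naive_ecdf(null_values, t):
    """Add-one ECDF #{v <= t} / (B + 1)."""
    return sum(1 for v in null_values if v <= t) / (len(null_values) + 1.0)


def naive_gcp_all_pairs(pvals, xi, null_bank):
    """GCP for every ordered threshold pair, from first principles.

    ``null_bank`` is a list of null p-value vectors (the permutation
    rows); CDFs are counting ECDFs over the bank's bin sums.
    """
    S = len(xi)
    out = []
    for i in range(S):
        for j in range(i + 1, S):
            lo1, hi1 = 0.0, xi[i]
            lo2, hi2 = xi[i], xi[j]
            t1, _ = naive_bin_sum(pvals, lo1, hi1)
            t2, _ = naive_bin_sum(pvals, lo2, hi2)
            null1 = [naive_bin_sum(row, lo1, hi1)[0] for row in null_bank]
            null2 = [naive_bin_sum(row, lo2, hi2)[0] for row in null_bank]
            f1 = naive_ecdf(null1, t1)
            f2 = naive_ecdf(null2, t2)
            out.append(-2.0 * (math.log(1.0 - f1) + math.log(1.0 - f2)))
    return out


def naive_agcp(pvals, xi, null_bank):
    return max(naive_gcp_all_pairs(pvals, xi, null_bank))


def brute_force_exhaustive_agcp_pvalue(x1, x2, xi):
    """Exact AGCP permutation p-value by full enumeration.

    Enumerates every n1-subset of the pooled rows, computes each
    labelling's marginal p-values by exact enumeration, builds the
    counting ECDFs from the full bank, evaluates the max statistic for
    the observed labelling and every bank row, and counts.
    """
    pooled = np.vstack([np.asarray(x1, float), np.asarray(x2, float)])
    n1 = len(x1)
    n, m = pooled.shape

    def pvec(subset):
        rows = list(subset) + [i for i in range(n) if i not in subset]
        relabelled = pooled[rows]
        return [
            enumerate_exact_pvalue(relabelled[:, k].tolist(), n1)
            for k in range(m)
        ]

    bank = [pvec(s) for s in itertools.combinations(range(n), n1)]
    observed = pvec(tuple(range(n1)))
    agcp0 = naive_agcp(observed, xi, bank)
    agcp_null = [naive_agcp(row, xi, bank) for row in bank]
    count = sum(1 for v in agcp_null if v >= agcp0)
    return count / len(bank)
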