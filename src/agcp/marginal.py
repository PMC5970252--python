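"""Per-variable (marginal) two-sample tests.

Each variable is tested on its own for a location difference between the
two groups, yielding one two-sided p-value per variable.  The default is
the Wilcoxon rank-sum test: exact (hypergeometric-rank null) for small
samples without ties, normal approximation with midranks and tie-corrected
variance otherwise.  A pooled-variance t-test is available as an
alternative marginal method.

Marginal p-values are never exactly zero — they feed ``ln p`` downstream —
so exact p-values are bounded below by the smallest attainable tail
probability and asymptotic ones by a positive machine floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .data import TwoSampleMatrix

__all__ = [
    "MarginalMethod",
    "default_method",
    "marginal_pvalues",
    "rank_cache",
    "ranksum_pvalue_table",
]

#: largest per-group size for which the exact rank-sum null is tabulated
EXACT_SIZE_LIMIT = 25

#: floor for asymptotic p-values (exact ones have their own attainable floor)
P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class MarginalMethod:
    """Choice of marginal test.

    ``wilcoxon_exact`` uses the exact null distribution of the rank-sum
    statistic and is only valid when ``min(n1, n2) <= 25``; columns with
    ties fall back automatically to the tie-corrected normal approximation.
    ``tie_policy`` is fixed at ``midrank``.
    """

    name: str
    tie_policy: str = "midrank"

    _VALID = ("wilcoxon_exact", "wilcoxon_normal", "t_test")

    def __post_init__(self) -> None:
        if self.name not in self._VALID:
            raise ValueError(f"unknown marginal method {self.name!r}; "
                             f"choose from {self._VALID}")
        if self.tie_policy != "midrank":
            raise ValueError("only the 'midrank' tie policy is supported")

    def validate_for(self, n1: int, n2: int) -> None:
        if self.name == "wilcoxon_exact" and min(n1, n2) > EXACT_SIZE_LIMIT:
            raise ValueError(
                f"wilcoxon_exact requires min(n1, n2) <= {EXACT_SIZE_LIMIT}; "
                "use wilcoxon_normal"
            )


def default_method(n1: int, n2: int) -> MarginalMethod:
    """Exact Wilcoxon for small groups, normal approximation otherwise."""
    if min(n1, n2) <= EXACT_SIZE_LIMIT:
        return MarginalMethod("wilcoxon_exact")
    return MarginalMethod("wilcoxon_normal")


def rank_cache(data: TwoSampleMatrix) -> np.ndarray:
    """Pooled per-column midranks, shape ``(n, m)``.

    Relabelling the groups permutes rows but leaves pooled ranks unchanged,
    so the ranks are computed once per dataset and reused for every
    permutation: the Wilcoxon statistic of any labelling is the sum of the
    cached ranks over that labelling's group-1 rows.
    """
    return stats.rankdata(data.pooled(), axis=0, method="average")


@lru_cache(maxsize=64)
def ranksum_pvalue_table(n1: int, n2: int) -> np.ndarray:
    """Exact two-sided p-values of the rank-sum statistic, indexed by W.

    ``table[w]`` is ``min(1, 2 * min(P(W <= w), P(W >= w)))`` under the
    null that the n1 group-1 ranks are a uniform random subset of
    ``{1, ..., n1+n2}`` (no ties).  W ranges over the attainable integers
    ``n1(n1+1)/2 .. n1(n1+n2) - n1(n1-1)/2``; the array covers ``0..max``.
    """
    n = n1 + n2
    w_max = n1 * (2 * n - n1 + 1) // 2  # sum of the n1 largest ranks
    # counts[j, s]: number of j-subsets of {1..i} with rank sum s
    counts = np.zeros((n1 + 1, w_max + 1))
    counts[0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(min(i, n1), 0, -1):
            counts[j, i:] += counts[j - 1, : w_max + 1 - i]
    pmf = counts[n1] / special.comb(n, n1)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(W >= w)
    table = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    return table


def _tie_statistics(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column tie diagnostics: (has_ties, sum of t^3 - t over tie groups)."""
    n, m = pooled.shape
    srt = np.sort(pooled, axis=0)
    # run-length encode equal neighbours column-wise
    tie_sum = np.zeros(m)
    has_ties = np.zeros(m, dtype=bool)
    for k in range(m):
        _, cnt = np.unique(srt[:, k], return_counts=True)
        if cnt.max() > 1:
            has_ties[k] = True
            tie_sum[k] = float(np.sum(cnt.astype(float) ** 3 - cnt))
    return has_ties, tie_sum


class WilcoxonConverter:
    """Maps group-1 rank sums to two-sided p-values, vectorised over columns.

    Built once per dataset; reused for the observed labelling and all
    permutations.  Columns without ties use the exact table when the
    method allows it; tied (or large-sample) columns use the midrank
    normal approximation with tie-corrected variance and no continuity
    correction.
    """

    def __init__(self, data: TwoSampleMatrix, method: MarginalMethod):
        method.validate_for(data.n1, data.n2)
        self.n1, self.n2 = data.n1, data.n2
        n = data.n
        self.has_ties, tie_sum = _tie_statistics(data.pooled())
        self.mu = self.n1 * (n + 1) / 2.0
        var = self.n1 * self.n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
        self.sigma = np.sqrt(np.maximum(var, 0.0))
        if method.name == "wilcoxon_exact":
            self.exact_cols = ~self.has_ties
            self.table = ranksum_pvalue_table(self.n1, self.n2)
        else:
            self.exact_cols = np.zeros(data.m, dtype=bool)
            self.table = None

    def __call__(self, w: np.ndarray) -> np.ndarray:
        """``w``: rank sums, shape ``(..., m)`` -> p-values, same shape."""
        w = np.asarray(w, dtype=float)
        p = np.empty_like(w)
        ex = self.exact_cols
        if ex.any():
            idx = np.rint(w[..., ex]).astype(np.intp)
            p[..., ex] = self.table[idx]
        ap = ~ex
        if ap.any():
            sigma = self.sigma[ap]
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(sigma > 0, (w[..., ap] - self.mu) / sigma, 0.0)
            pa = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
            # a column whose pooled values are all equal carries no evidence
            pa = np.where(sigma > 0, pa, 1.0)
            p[..., ap] = np.maximum(pa, P_FLOOR)
        return p


def _ttest_pvalues(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t-test, two-sided, vectorised by column."""
    n1, n2 = x1.shape[0], x2.shape[0]
    df = n1 + n2 - 2
    s1 = x1.var(axis=0, ddof=1)
    s2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} column(s) with zero pooled variance; "
            "emitting p = 1 for them",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, denom))
    p = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where(degenerate, 1.0, p)
    return np.maximum(p, P_FLOOR)


def marginal_pvalues(
    data: TwoSampleMatrix, method: MarginalMethod | None = None
) -> np.ndarray:
    """Two-sided marginal p-values, one per variable.

    Parameters
    ----------
    data : TwoSampleMatrix
    method : MarginalMethod, optional
        Defaults to exact Wilcoxon when ``min(n1, n2) <= 25``, otherwise
        the normal approximation.

    Returns
    -------
    ndarray of shape (m,), entries in (0, 1].
    """
    if method is None:
        method = default_method(data.n1, data.n2)
    if method.name == "t_test":
        return _ttest_pvalues(data.x1, data.x2)
    conv = WilcoxonConverter(data, method)
    w = rank_cache(data)[: data.n1].sum(axis=0)
    return conv(w)
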