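"""Group-combined p-value (GCP) statistics and their adaptive maximum.

For an ordered pair of thresholds ``(xi_s1, xi_s2)`` the marginal p-values
are split into a strong group (``p < xi_s1``) and a moderate group
(``xi_s1 <= p < xi_s2``); p-values at or above ``xi_s2`` are discarded.
Each group is Fisher-combined into ``T = -2 * sum(ln p)``, mapped through
its permutation-null CDF, and the two transformed groups are added:

    GCP(xi_s1, xi_s2) = -2 ln(1 - F_s1(T1)) - 2 ln(1 - F_s2(T2))

The adaptive statistic AGCP is the maximum of GCP over all ordered
threshold pairs from a candidate set; with the recommended seven
thresholds that is C(7, 2) = 21 pairs.

Null CDFs are empirical, built from a bank of B permuted p-value vectors,
with the add-one convention ``F(t) = #{T_b <= t} / (B + 1)`` so that
``1 - F >= 1/(B+1)`` and every GCP value is finite.  The same convention
is applied to observed and permuted statistics, which keeps the final
permutation p-value exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ThresholdSet",
    "EmpiricalCdfTable",
    "group_statistic",
    "ecdf_value",
    "bin_log_sums",
    "gcp_statistic",
    "agcp_statistic",
]

#: recommended candidate thresholds (21 ordered pairs)
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 1.0)


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered candidate cut-points ``xi_1 < ... < xi_S`` in (0, 1]."""

    xi: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        xi = tuple(sorted(set(float(x) for x in self.xi)))
        if len(xi) < 2:
            raise ValueError("need at least two distinct thresholds")
        if xi[0] <= 0 or xi[-1] > 1:
            raise ValueError("thresholds must lie in (0, 1]")
        object.__setattr__(self, "xi", xi)

    @property
    def S(self) -> int:
        return len(self.xi)

    def pairs(self) -> list[tuple[int, int]]:
        """All ordered index pairs (s1, s2) with s1 < s2, lexicographic."""
        return [(i, j) for i in range(self.S) for j in range(i + 1, self.S)]

    def pair_values(self) -> list[tuple[float, float]]:
        return [(self.xi[i], self.xi[j]) for i, j in self.pairs()]


def group_statistic(p: np.ndarray, lo: float, hi: float) -> tuple[float, int]:
    """Fisher sum ``-2 sum(ln p)`` over the half-open bin ``[lo, hi)``.

    ``lo = 0`` is the sentinel for the first group (all ``p < hi``, since
    p-values are strictly positive).  The upper bound is strict, the lower
    non-strict.  An empty bin yields ``(0.0, 0)``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p-values must be strictly positive")
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    mask = (p >= lo) & (p < hi)
    if not mask.any():
        return 0.0, 0
    return float(-2.0 * np.log(p[mask]).sum()), int(mask.sum())


def ecdf_value(sorted_null: np.ndarray, t: float) -> float:
    """Add-one empirical CDF ``#{T_b <= t} / (B + 1)`` of a sorted null."""
    sorted_null = np.asarray(sorted_null)
    b = sorted_null.shape[0]
    return float(np.searchsorted(sorted_null, t, side="right")) / (b + 1)


def bin_log_sums(p: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Cumulative Fisher sums ``A[..., s] = -2 sum_k ln(p_k) I(p_k < xi_s)``.

    ``p`` has shape ``(..., m)``; the result has shape ``(..., S)``.  The
    two bin statistics of any pair follow as ``T1 = A[..., s1]`` and
    ``T2 = A[..., s2] - A[..., s1]``.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if np.any(p <= 0):
        raise ValueError("p-values must be strictly positive")
    rows, m = p.shape[0], p.shape[-1]
    xi = np.asarray(thresholds.xi)
    s_count = thresholds.S
    # c[k] = number of thresholds <= p_k; p_k contributes to bins s >= c[k]
    c = np.searchsorted(xi, p.reshape(rows, m), side="right")
    w = -2.0 * np.log(p.reshape(rows, m))
    flat = (np.arange(rows)[:, None] * (s_count + 1) + c).ravel()
    per_bin = np.bincount(flat, weights=w.ravel(),
                          minlength=rows * (s_count + 1))
    per_bin = per_bin.reshape(rows, s_count + 1)[:, :s_count]
    return np.cumsum(per_bin, axis=1)


class EmpiricalCdfTable:
    """Sorted permutation-null values of T1 and T2 for every threshold pair.

    Built from the bank's bin sums ``null_A`` (shape ``(B, S)``).  T1
    depends on ``s1`` only; T2 on the pair.
    """

    def __init__(self, null_A: np.ndarray, thresholds: ThresholdSet):
        null_A = np.asarray(null_A, dtype=float)
        if null_A.ndim != 2 or null_A.shape[1] != thresholds.S:
            raise ValueError("null_A must have shape (B, S)")
        self.thresholds = thresholds
        self.B = null_A.shape[0]
        self._pairs = thresholds.pairs()
        self._t1_sorted = [np.sort(null_A[:, i]) for i in range(thresholds.S)]
        self._t2_sorted = [
            np.sort(null_A[:, j] - null_A[:, i]) for i, j in self._pairs
        ]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(self._pairs)

    def null_for_pair(self, pair: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Sorted null vectors (T1, T2) for an ordered index pair."""
        try:
            k = self._pairs.index(pair)
        except ValueError as exc:
            raise KeyError(f"pair {pair} not in the threshold table") from exc
        return self._t1_sorted[pair[0]], self._t2_sorted[k]

    def gcp_values(self, A: np.ndarray) -> np.ndarray:
        """GCP for every pair, vectorised over rows of bin sums.

        ``A`` has shape ``(R, S)``; returns shape ``(R, n_pairs)`` with the
        pairs in lexicographic order.
        """
        A = np.atleast_2d(np.asarray(A, dtype=float))
        denom = self.B + 1.0
        out = np.empty((A.shape[0], len(self._pairs)))
        for k, (i, j) in enumerate(self._pairs):
            f1 = np.searchsorted(self._t1_sorted[i], A[:, i], side="right") / denom
            f2 = np.searchsorted(
                self._t2_sorted[k], A[:, j] - A[:, i], side="right"
            ) / denom
            out[:, k] = -2.0 * (np.log1p(-f1) + np.log1p(-f2))
        return out


def gcp_statistic(
    p: np.ndarray, pair: tuple[int, int], cdfs: EmpiricalCdfTable
) -> float:
    """GCP of one ordered threshold pair for a marginal p-value vector."""
    A = bin_log_sums(p, cdfs.thresholds)
    k = cdfs.pairs.index(tuple(pair))
    return float(cdfs.gcp_values(A)[0, k])


def agcp_statistic(
    p: np.ndarray, thresholds: ThresholdSet, cdfs: EmpiricalCdfTable
) -> tuple[float, tuple[float, float]]:
    """Adaptive maximum of GCP over all ordered pairs.

    Returns ``(agcp, (xi_s1, xi_s2))``; ties go to the lexicographically
    smallest pair (``np.argmax`` keeps the first maximum).
    """
    if tuple(thresholds.xi) != tuple(cdfs.thresholds.xi):
        raise ValueError("threshold set does not match the CDF table")
    g = cdfs.gcp_values(bin_log_sums(p, thresholds))[0]
    k = int(np.argmax(g))
    i, j = cdfs.pairs[k]
    return float(g[k]), (thresholds.xi[i], thresholds.xi[j])
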