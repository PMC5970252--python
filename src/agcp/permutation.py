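"""One-layer permutation calibration of the AGCP test.

A single bank of B group-label permutations serves two purposes: its
marginal p-value vectors define the empirical null CDFs of the per-group
Fisher sums, and the same vectors — pushed through those CDFs — form the
null distribution of the adaptive maximum.  This avoids the nested
(two-layer) resampling a naive calibration of the max statistic would
require.

The permutation p-value follows the literal counting estimator

    p = #{AGCP_b >= AGCP_0 : b = 1..B} / B

so p = 0 is attainable under random permutation; an optional add-one
correction ((count + 1)/(B + 1)) is available behind a flag.  With the
exhaustive scheme the identity labelling is one of the rows, so the test
is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data import TwoSampleMatrix
from .gcp import EmpiricalCdfTable, ThresholdSet, bin_log_sums
from .marginal import (
    MarginalMethod,
    WilcoxonConverter,
    default_method,
    marginal_pvalues,
    rank_cache,
)

__all__ = [
    "PermutationScheme",
    "NullPValueBank",
    "AgcpResult",
    "build_null_bank",
    "agcp_test",
]

#: refuse exhaustive enumeration beyond this many labellings
EXHAUSTIVE_CAP = 200_000


@dataclass(frozen=True)
class PermutationScheme:
    """How the bank of relabelled datasets is drawn.

    ``random_subsets`` draws B independent uniform n1-subsets of the pooled
    rows (the identity labelling may occur); ``exhaustive`` enumerates all
    C(n, n1) labellings and ignores ``B``.
    """

    mode: str = "random_subsets"
    B: int = 10_000
    exhaustive_cap: int = EXHAUSTIVE_CAP

    def __post_init__(self) -> None:
        if self.mode not in ("random_subsets", "exhaustive"):
            raise ValueError("mode must be 'random_subsets' or 'exhaustive'")
        if self.mode == "random_subsets" and self.B < 1:
            raise ValueError("B must be >= 1")

    def subsets(self, n1: int, n2: int, rng: np.random.Generator) -> np.ndarray:
        """Row-index matrix of group-1 subsets, shape (B, n1)."""
        n = n1 + n2
        if self.mode == "exhaustive":
            total = int(special.comb(n, n1, exact=True))
            if total > self.exhaustive_cap:
                raise ValueError(
                    f"C({n}, {n1}) = {total} labellings exceed the cap "
                    f"{self.exhaustive_cap}; use mode='random_subsets'"
                )
            return np.array(list(itertools.combinations(range(n), n1)),
                            dtype=np.intp)
        u = rng.random((self.B, n))
        return np.argpartition(u, n1 - 1, axis=1)[:, :n1].astype(np.intp)


@dataclass(frozen=True)
class NullPValueBank:
    """B x m matrix of marginal p-values from relabelled datasets."""

    P: np.ndarray
    B: int
    seed: int | None
    subsets: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class AgcpResult:
    """Outcome of the AGCP permutation test."""

    agcp0: float
    gcp_by_pair: np.ndarray
    pair_thresholds: tuple[tuple[float, float], ...]
    argmax_pair: tuple[float, float]
    pvalue: float
    B: int
    marginal_pvalues: np.ndarray
    null_agcp: np.ndarray = field(repr=False, default=None)


def _indicator(subsets: np.ndarray, n: int) -> np.ndarray:
    ind = np.zeros((subsets.shape[0], n))
    np.put_along_axis(ind, subsets, 1.0, axis=1)
    return ind


def _ttest_pvalues_from_subsets(
    pooled: np.ndarray, subsets: np.ndarray, n1: int
) -> np.ndarray:
    """Pooled-variance t-test p-values for many labellings at once."""
    from scipy import stats

    n, _ = pooled.shape
    n2 = n - n1
    df = n - 2
    ind = _indicator(subsets, n)
    tot = pooled.sum(axis=0)
    tot2 = (pooled ** 2).sum(axis=0)
    s1 = ind @ pooled
    q1 = ind @ (pooled ** 2)
    mean1 = s1 / n1
    mean2 = (tot - s1) / n2
    ss1 = q1 - n1 * mean1 ** 2
    ss2 = (tot2 - q1) - n2 * mean2 ** 2
    sp2 = (ss1 + ss2) / df
    denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mean1 - mean2) / np.where(denom > 0, denom, 1.0), 0.0)
    p = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where(denom > 0, p, 1.0)
    return np.maximum(p, np.finfo(float).tiny)


def build_null_bank(
    data: TwoSampleMatrix,
    method: MarginalMethod | None = None,
    scheme: PermutationScheme | None = None,
    seed: int | None = None,
) -> NullPValueBank:
    """Marginal p-values for B relabelled copies of the data.

    Pooled midranks are computed once (label permutation leaves them
    unchanged) and rank sums for all labellings are obtained by one matrix
    product, so the cost per permutation is O(n * m) multiplications.
    """
    if method is None:
        method = default_method(data.n1, data.n2)
    if scheme is None:
        scheme = PermutationScheme()
    rng = np.random.default_rng(seed)
    subsets = scheme.subsets(data.n1, data.n2, rng)
    if method.name == "t_test":
        P = _ttest_pvalues_from_subsets(data.pooled(), subsets, data.n1)
    else:
        conv = WilcoxonConverter(data, method)
        ranks = rank_cache(data)
        w = _indicator(subsets, data.n) @ ranks
        P = conv(w)
    return NullPValueBank(P=P, B=subsets.shape[0], seed=seed, subsets=subsets)


def agcp_test(
    data: TwoSampleMatrix,
    thresholds: ThresholdSet | None = None,
    method: MarginalMethod | None = None,
    scheme: PermutationScheme | None = None,
    seed: int | None = None,
    add_one: bool = False,
) -> AgcpResult:
    """Run the full AGCP test with one-layer permutation calibration.

    Steps: marginal p-values of the observed labelling (b = 0); a bank of
    B permuted p-value vectors (b = 1..B); empirical CDFs of the per-group
    Fisher sums from rows 1..B; AGCP_b for b = 0..B against those CDFs;
    p-value by counting null maxima at or above the observed one.

    Parameters
    ----------
    add_one : bool
        If true, report ``(count + 1) / (B + 1)`` instead of ``count / B``.
    """
    if thresholds is None:
        thresholds = ThresholdSet()
    if method is None:
        method = default_method(data.n1, data.n2)
    if scheme is None:
        scheme = PermutationScheme()
    if scheme.mode == "random_subsets" and scheme.B < 1:
        raise ValueError("B must be >= 1")

    p0 = marginal_pvalues(data, method)
    bank = build_null_bank(data, method, scheme, seed)

    A_null = bin_log_sums(bank.P, thresholds)
    A_obs = bin_log_sums(p0, thresholds)
    cdfs = EmpiricalCdfTable(A_null, thresholds)

    g_obs = cdfs.gcp_values(A_obs)[0]
    agcp_null = cdfs.gcp_values(A_null).max(axis=1)
    k = int(np.argmax(g_obs))
    agcp0 = float(g_obs[k])

    count = int(np.sum(agcp_null >= agcp0))
    if add_one:
        pvalue = (count + 1) / (bank.B + 1)
    else:
        pvalue = count / bank.B

    pair_values = tuple(thresholds.pair_values())
    return AgcpResult(
        agcp0=agcp0,
        gcp_by_pair=g_obs,
        pair_thresholds=pair_values,
        argmax_pair=pair_values[k],
        pvalue=float(pvalue),
        B=bank.B,
        marginal_pvalues=p0,
        null_agcp=agcp_null,
    )
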