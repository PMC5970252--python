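# Methods

## The testing problem

Given two independent samples `X11..X1n1 ~ F1(x - mu1)` and
`X21..X2n2 ~ F2(x - mu2)` of m-variate observations with `m >> n`, the
global null is `H0: mu1 = mu2`. Classical Hotelling-type statistics fail
here because the pooled covariance cannot be inverted (or estimated) when
m exceeds n; U-statistic mean tests (Chen–Qin and relatives) avoid the
inversion but lean on asymptotic normality and moment conditions linking
m and n. The route taken in this package is marginal: test each variable
on its own, then combine the m p-values.

## The AGCP statistic

For a candidate threshold set `xi_1 < ... < xi_S` in (0, 1] and an ordered
pair `(xi_s1, xi_s2)`, the marginal p-values are split into a strong group
(`p_k < xi_s1`) and a moderate group (`xi_s1 <= p_k < xi_s2`); p-values at
or above `xi_s2` are discarded as noise that would only add variance. Each
group is Fisher-combined,

    T1 = -2 * sum_k ln(p_k) * I(p_k < xi_s1)
    T2 = -2 * sum_k ln(p_k) * I(xi_s1 <= p_k < xi_s2),

and standardised through its own null CDF before the two groups are added:

    GCP(xi_s1, xi_s2) = -2 ln(1 - F_s1(T1)) - 2 ln(1 - F_s2(T2)).

The CDF transform is what makes the two groups commensurable: T1 and T2
have very different null scales (the strong bin is usually empty or nearly
so), and `-2 ln(1 - F(T))` maps each onto a common exponential-like scale.
An empty bin contributes `T = 0` evaluated through the same CDF — no
special-casing, because under the null most permutations also leave the
bin empty and the transform accounts for exactly that mass.

Because the best pair of thresholds depends on the unknown signal sparsity
and strength, the adaptive statistic maximises over all `C(S, 2)` ordered
pairs:

    AGCP = max_{s1 < s2} GCP(xi_s1, xi_s2).

The default candidate set is `{0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 1}`
(21 pairs). These cut-points are the conventional grid of the truncated
p-value combination literature; 0.2 is the usual upper truncation bound
(larger p-values carry almost no signal), and 1 admits a pair that keeps
everything. With `S = 2` the statistic reduces to a fixed-threshold
group-combined test. Ties in the maximum resolve to the lexicographically
smallest pair; this only affects the reported argmax, not the p-value.

## One-layer permutation calibration

Both the group CDFs `F_s1, F_s2` and the null distribution of the max are
unknown, and a naive calibration would nest one resampling loop inside
another. The one-layer scheme reuses a single bank of B group-label
permutations for both purposes:

1. marginal p-values of the observed labelling (`b = 0`);
2. marginal p-values of B relabelled datasets (`b = 1..B`), each a uniform
   random n1-subset of the pooled rows (drawn independently, with the
   identity labelling allowed; an exhaustive mode enumerates all
   `C(n, n1)` labellings when that count is below a cap);
3. empirical CDFs of T1 and T2 for every pair, from rows `1..B` only;
4. AGCP_b for `b = 0..B` against those shared CDFs;
5. `p = #{AGCP_b >= AGCP_0, b = 1..B} / B`.

The ECDF uses the add-one convention `F(t) = #{T_b <= t} / (B + 1)`, so
`1 - F >= 1/(B+1)` and every GCP value is finite; the identical convention
is applied to the observed and permuted rows, which preserves the
exchangeability that the final counting p-value relies on. The p-value is
the literal `count / B` estimator, so 0 is attainable under random
permutation; an add-one corrected `(count+1)/(B+1)` is available behind a
flag. Rejection in the simulation studies uses `p <= alpha`, because
attainable p-values sit on the lattice `k/B` and a strict inequality would
undercount at lattice points.

With very small, very discrete problems (say 5 per group and few
variables) the attainable marginal p-grid is so coarse that most
thresholds are dead and AGCP ties heavily across labellings; the test then
becomes conservative, never anti-conservative.

### Cost

Pooled midranks are computed once per dataset: relabelling never changes
them, so the Wilcoxon rank sum of every permutation is a single
indicator-matrix product (`(B+1) x n` by `n x m`). The exact rank-sum null
is tabulated once per `(n1, n2)` by dynamic programming and shared by all
m columns and all permutations. One AGCP test at `n = 25` per group,
`m = 200`, `B = 2000` runs in ~50 ms; a 500-replicate study cell in
well under a minute.

## Marginal tests

Default: two-sided Wilcoxon rank-sum. Exact (hypergeometric-rank null)
when `min(n1, n2) <= 25` and the column has no ties; otherwise the normal
approximation with midranks, tie-corrected variance and no continuity
correction. Two-sided p is `min(1, 2 * min(lower tail, upper tail))`.
Exact p-values are bounded below by the smallest attainable tail
probability (`2/C(n, n1)` for equal groups); asymptotic ones are floored
at the smallest positive double, since `ln p` feeds the combination
directly. A pooled-variance t-test is available behind the same contract;
columns with zero pooled variance are flagged and emit `p = 1`.

The marginal p-values of observed and permuted datasets are computed
analytically; the B permutations supply the null p-value *vectors*, not
the marginal p-values themselves. A strict permutation-proportion marginal
(granularity 1/B) would cost a factor B more or require reusing the bank
column-wise; the analytic route is the package's reading of the procedure
and is the one all calibration results here are computed under.

## Synthetic data generators

The study grid uses `n1 = n2 = n in {10, 25, 50}`, `m in {100, 200}`,
`alpha = 0.05`, group 2 centred at 0 with identity covariance.

**Covariance templates** for group 1: DS1 compound symmetry
(`sigma_uv = 0.5`, unit diagonal); DS2 geometric decay
(`sigma_uv = 0.5^|u-v|`); DS3 the DS2 decay with a two-block diagonal
(variances 1 on the first m/2 coordinates, 3 on the rest; m even). All
three are positive definite at every supported dimension (Cholesky-checked
in the tests).

**Models.**

* MVN: group 1 `N(mu1, Sigma1)`, group 2 `N(0, I)`.
* MVT, 4 df: one chi-square mixing variable per subject. By default the
  scatter argument is the t *scale* matrix — the parametrisation of
  standard multivariate-t samplers — so the realised covariance is
  `2 * Sigma` at 4 df. This default was fixed by cross-checking the
  Chen–Qin comparator's power against its published values, which the
  exact-covariance mode contradicts by a factor-2 signal-to-noise shift;
  an exact-covariance mode (`sigma_is_covariance=True`) is provided.
* MA: `X_k = sum_l rho_l Z_{k+l-1} + mu_k` with one innovation vector of
  length 2m-1 per subject; innovations `Z_j` are centred Gamma(4, 1)
  (variance 4, skewed) for `j <= m/2` and standard normal beyond. The
  Gamma block is assigned to innovation *indices* 1..m/2 — the only
  reading that covers all 2m-1 consumed indices without inventing a
  second Gamma block. Full dependence (FD) draws every coefficient from
  U(2, 3); partial dependence (PD) keeps only the first three nonzero,
  giving a banded covariance (independence beyond lag 2). Coefficients
  are drawn once per study from a seed derived from the master seed and
  frozen across replicates. Both groups share the MA process (the
  identity-covariance convention for group 2 cannot apply here), so the
  exact MA covariance — computed analytically from the coefficients and
  innovation variances — enters the signal calibration for both traces.

**Signal calibration.** Under the alternative, `mu1` has
`L = floor(m^gamma)` nonzero leading entries (equal, or linearly
increasing), scaled so that

    eta = ||mu1 - mu2||^2 / sqrt(tr(Sigma1^2) + tr(Sigma2^2))

hits the requested value exactly (round-trip verified to 1e-10). Placing
the signal at the *first* L coordinates is a documented choice: under DS3
it puts the shifts in the low-variance block; the allocation is
configurable because this placement materially affects power and the
choice is not dictated by the model.

What these generators do not emulate: real microarray data are
non-Gaussian in ways beyond heavy tails (batch effects, intensity-
dependent variance, probe-level correlation), carry ties after
quantisation, and have unequal group sizes. Passing the simulation suite
therefore shows correct calibration and ordering under the three stated
models, not performance guarantees on any particular real dataset.

## Chen–Qin comparator

`Tn` removes the diagonal terms `X_ij' X_ij` from the squared mean gap, so
`E[Tn] = ||mu1 - mu2||^2` without any covariance inversion; its null SD is
estimated with the canonical leave-two-out trace estimators of
`tr(Sigma_i^2)` and `tr(Sigma1 Sigma2)`, and the test rejects in the upper
normal tail (one-sided — the target `||mu1 - mu2||^2` is nonnegative).
The implementation is validated by the algebraic identity
`Tn = ||Xbar1 - Xbar2||^2 - tr(S1)/n1 - tr(S2)/n2`, which an independent
test recomputes directly. A non-positive variance estimate (possible at
very small n) raises rather than being clamped. The mild null inflation
of CQ at n = 10 under compound symmetry is a property of its asymptotic
calibration and is reproduced, not corrected.

## Study runner and reproducibility

A study grid point is a frozen config (model, n, m, structure, gamma,
eta, allocation, reps, B, alpha, seed, test registry). Replicate r draws
its data from a `SeedSequence` stream keyed by `(seed, stream-id, r)` and
its permutation bank from a separate keyed stream, so results are
identical across runs and independent of execution order; the whole study
is reproducible from the config alone. Failed replicates are recorded and
excluded with a warning, never silently dropped. Reported per cell:
rejection count, rate, and binomial Monte-Carlo SE.

Reduced default scale in the packaged tests: 500 replicates with
B = 2000 (the reference scale is 1000 x 10000). At 500 replicates the SE
of a rate near 0.05 is 0.010 and near 0.4 is 0.022, which is the
resolution all packaged comparisons are stated at.

## Numerical notes and limitations

* Exact Wilcoxon tables are float DP over subset counts; for
  `min(n1, n2) <= 25` the counts are far below the 2^53 integer limit.
* `bin_log_sums` assigns each p-value to its threshold cell with a
  `searchsorted` and accumulates `-2 ln p` by bincount; bin membership is
  strict on the upper bound, non-strict on the lower, and `p = 1` falls
  in no bin (consistent with thresholds capped at 1).
* GCP is monotone in each bin's CDF value and weakly increasing when any
  in-bin p-value shrinks; both properties are property-tested.
* The permutation p-value at B = 2000 has granularity 5e-4; studies at
  alpha = 0.05 are insensitive to this, single-dataset analyses near a
  decision boundary should raise B.
* The test is calibrated by permutation and hence assumes the two groups
  are exchangeable under the null; with markedly different group
  covariances the size can drift a few points from nominal, matching the
  published behaviour.
* J = 3 p-value groups (two used, one discarded) is fixed; generalising
  the group count is out of scope.
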