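"""Synthetic two-sample generators for the power/size study.

Three sampling models are provided:

* multivariate normal, group 1 ~ N(mu1, Sigma1), group 2 ~ N(0, I);
* multivariate t with 4 degrees of freedom and the same location/scatter
  pairs, with the scatter interpreted by default as the t *scale* matrix
  (as in standard multivariate-t samplers; an exact-covariance mode is
  available);
* a moving-average process X_k = sum_l rho_l Z_{k+l-1} + mu_k whose
  innovations mix centred Gamma(4, 1) (variance 4, skewed) and standard
  normal terms.

Covariance templates: DS1 is compound symmetry (0.5 off-diagonal), DS2 is
the geometric decay 0.5^|u-v|, DS3 adds a two-block heterogeneous diagonal
(variances 1 and 3) to the DS2 decay.

Signal strength is calibrated through
``eta = ||mu1 - mu2||^2 / sqrt(tr(Sigma1^2) + tr(Sigma2^2))`` with mu2 = 0,
placing L = floor(m^gamma) nonzero entries at the first L coordinates,
either all equal or linearly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "build_covariance",
    "signal_length",
    "allocate_means",
    "simulate_mvn",
    "simulate_mvt",
    "draw_ma_coefficients",
    "ma_covariance",
    "simulate_ma",
]

COV_STRUCTURES = ("DS1", "DS2", "DS3", "identity")


def build_covariance(structure: str, m: int) -> np.ndarray:
    """Covariance template for group 1.

    DS1: unit diagonal, 0.5 everywhere off-diagonal.  DS2: 0.5^|u-v|.
    DS3: DS2 off-diagonal with variances 1 on the first half of the
    coordinates and 3 on the second half (m must be even).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if structure == "identity":
        return np.eye(m)
    if structure == "DS1":
        sigma = np.full((m, m), 0.5)
        np.fill_diagonal(sigma, 1.0)
        return sigma
    lag = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    sigma = 0.5 ** lag.astype(float)
    if structure == "DS2":
        return sigma
    if structure == "DS3":
        if m % 2:
            raise ValueError("DS3 requires even m (two equal variance blocks)")
        diag = np.where(np.arange(m) < m // 2, 1.0, 3.0)
        np.fill_diagonal(sigma, diag)
        return sigma
    raise ValueError(f"unknown covariance structure {structure!r}")


def signal_length(m: int, gamma: float) -> int:
    """Number of shifted coordinates, L = floor(m^gamma)."""
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1)")
    return int(np.floor(m ** gamma))


def allocate_means(
    m: int,
    gamma: float,
    eta: float,
    allocation: str,
    sigma1: np.ndarray,
    sigma2: np.ndarray,
) -> np.ndarray:
    """Mean vector mu1 with L = floor(m^gamma) nonzero leading entries.

    The entries are scaled so that ``||mu1||^2`` equals
    ``eta * sqrt(tr(Sigma1^2) + tr(Sigma2^2))`` exactly; ``equal`` makes
    them constant, ``linear`` proportional to 1, 2, ..., L.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    mu = np.zeros(m)
    if eta == 0:
        return mu
    L = signal_length(m, gamma)
    target = eta * np.sqrt(
        np.sum(np.asarray(sigma1) ** 2) + np.sum(np.asarray(sigma2) ** 2)
    )
    if allocation == "equal":
        mu[:L] = np.sqrt(target / L)
    elif allocation == "linear":
        ell = np.arange(1, L + 1, dtype=float)
        c = np.sqrt(target / np.sum(ell ** 2))
        mu[:L] = c * ell
    else:
        raise ValueError("allocation must be 'equal' or 'linear'")
    return mu


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_mvn(n1, n2, mu1, sigma1, seed=None):
    """Group 1 ~ N(mu1, Sigma1), group 2 ~ N(0, I).  Returns TwoSampleMatrix."""
    from .data import TwoSampleMatrix

    rng = _as_rng(seed)
    mu1 = np.asarray(mu1, dtype=float)
    m = mu1.shape[0]
    chol = np.linalg.cholesky(np.asarray(sigma1, dtype=float))
    x1 = mu1 + rng.standard_normal((n1, m)) @ chol.T
    x2 = rng.standard_normal((n2, m))
    return TwoSampleMatrix(x1, x2)


def simulate_mvt(n1, n2, mu1, sigma1, df=4, seed=None, sigma_is_covariance=False):
    """Multivariate t draws with location mu1/0 and scatter Sigma1/I.

    By default Sigma is the *scale* matrix of the t distribution, the
    parametrisation of standard multivariate-t samplers (the covariance of
    the draws is then ``Sigma * df / (df - 2)``).  With
    ``sigma_is_covariance=True`` the scatter is rescaled by (df - 2)/df so
    that the covariance of the draws equals Sigma exactly.
    """
    from .data import TwoSampleMatrix

    if df <= 2:
        raise ValueError("df must exceed 2 for the covariance to exist")
    rng = _as_rng(seed)
    mu1 = np.asarray(mu1, dtype=float)
    m = mu1.shape[0]
    factor = (df - 2.0) / df if sigma_is_covariance else 1.0
    chol = np.linalg.cholesky(np.asarray(sigma1, dtype=float) * factor)

    def draw(n, mu, chol_scale):
        g = rng.standard_normal((n, m)) @ chol_scale.T
        w = rng.chisquare(df, size=n) / df
        return mu + g / np.sqrt(w)[:, None]

    x1 = draw(n1, mu1, chol)
    x2 = draw(n2, 0.0, np.eye(m) * np.sqrt(factor))
    return TwoSampleMatrix(x1, x2)


@dataclass(frozen=True)
class MaSpec:
    """Frozen moving-average coefficients and innovation profile.

    ``rho`` has length m.  Full dependence (FD) draws every coefficient
    from U(2, 3); partial dependence (PD) keeps only the first three
    nonzero, so coordinates further than 2 apart are independent.
    Innovation variances: 4 (centred Gamma(4, 1)) for indices 1..m/2,
    1 (standard normal) beyond.
    """

    rho: tuple[float, ...]
    dependence: str

    @property
    def m(self) -> int:
        return len(self.rho)


def draw_ma_coefficients(m: int, dependence: str, seed=None) -> MaSpec:
    """Draw the MA coefficient vector once (to be frozen across a study)."""
    rng = _as_rng(seed)
    if dependence == "FD":
        rho = rng.uniform(2.0, 3.0, size=m)
    elif dependence == "PD":
        rho = np.zeros(m)
        rho[:3] = rng.uniform(2.0, 3.0, size=3)
    else:
        raise ValueError("dependence must be 'FD' or 'PD'")
    return MaSpec(rho=tuple(rho), dependence=dependence)


def _innovation_variances(m: int) -> np.ndarray:
    """Var(Z_j) for the 2m-1 innovation indices consumed by the window."""
    var = np.ones(2 * m - 1)
    var[: m // 2] = 4.0
    return var


def _window_matrix(rho: np.ndarray, m: int) -> np.ndarray:
    """R with R[k, k+l-1] = rho_l (0-based) so that X = Z @ R.T."""
    R = np.zeros((m, 2 * m - 1))
    for k in range(m):
        R[k, k : k + m] = rho
    return R


def ma_covariance(spec: MaSpec) -> np.ndarray:
    """Exact covariance of the MA process implied by the coefficients.

    ``sigma[k1, k2] = sum_j rho_{j-k1} rho_{j-k2} Var(Z_j)`` over the
    innovation indices j shared by both coordinate windows.
    """
    rho = np.asarray(spec.rho)
    m = spec.m
    R = _window_matrix(rho, m)
    return (R * _innovation_variances(m)) @ R.T


def simulate_ma(n1, n2, mu1, spec: MaSpec, seed=None):
    """Both groups from the same MA process; group 1 shifted by mu1."""
    from .data import TwoSampleMatrix

    rng = _as_rng(seed)
    mu1 = np.asarray(mu1, dtype=float)
    m = spec.m
    if mu1.shape[0] != m:
        raise ValueError("mu1 length must match the coefficient vector")
    R = _window_matrix(np.asarray(spec.rho), m)
    gamma_cols = m // 2

    def draw(n, mu):
        z = np.empty((n, 2 * m - 1))
        z[:, :gamma_cols] = rng.gamma(4.0, 1.0, size=(n, gamma_cols)) - 4.0
        z[:, gamma_cols:] = rng.standard_normal((n, 2 * m - 1 - gamma_cols))
        return mu + z @ R.T

    return TwoSampleMatrix(draw(n1, mu1), draw(n2, 0.0))
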