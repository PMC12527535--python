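"""Influence-function-based inference: SEs, Wald CIs, simultaneous bands.

Each estimator returns, along with its point estimate, a mean-zero
per-observation influence-function (IF) vector.  The empirical second moment
of the IF yields the standard error; asymptotic normality of the estimators
gives closed-form Wald intervals.  When several subgroup effects are
estimated jointly, a sup-t simultaneous confidence band is built from the
estimated IF correlation matrix: the critical value is the level-quantile of
max_j |Z_j| with Z multivariate normal with that correlation, so the band
covers all subgroup effects simultaneously at the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["wald_interval", "if_se", "simultaneous_band", "BandResult"]


def wald_interval(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """estimate +/- z_{(1+level)/2} * se."""
    if se < 0:
        raise ValueError("se must be non-negative")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return estimate - z * se, estimate + z * se


def if_se(if_values: np.ndarray) -> float:
    """Standard error sqrt(mean(if^2) / n) of an estimating-equation estimator.

    ``n`` is the length of the IF vector: the multi-source size N for internal
    analyses, N + n0 for external ones.
    """
    v = np.asarray(if_values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 influence values")
    return float(np.sqrt(np.mean(v * v) / n))


@dataclass
class BandResult:
    """A sup-t simultaneous confidence band over K jointly estimated effects."""

    lower: np.ndarray
    upper: np.ndarray
    crit: float
    draws: int
    seed: int
    repaired: bool = False  # correlation eigenvalues floored


def _corr_from_cov(cov: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    sd = np.where(sd > 0, sd, 1.0)
    corr = cov / np.outer(sd, sd)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    w, v = np.linalg.eigh(corr)
    repaired = bool(w.min() < 1e-10)
    if repaired:
        w = np.clip(w, 1e-10, None)
        corr = (v * w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr, repaired


def sup_t_critical(corr: np.ndarray, level: float, draws: int, seed: int) -> float:
    """Level-quantile of max_j |Z_j| for Z ~ N(0, corr), by Monte Carlo."""
    K = corr.shape[0]
    if K == 1:
        return float(stats.norm.ppf(0.5 * (1.0 + level)))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(K))
    Z = rng.standard_normal((draws, K)) @ L.T
    return float(np.quantile(np.max(np.abs(Z), axis=1), level))


def simultaneous_band(
    estimates: np.ndarray,
    if_matrix: np.ndarray,
    level: float = 0.95,
    draws: int = 10_000,
    seed: int = 0,
) -> BandResult:
    """Sup-t band for K estimates from their n x K influence-function matrix.

    The covariance of the estimates is mean(if_j * if_k) / n; its correlation
    drives the critical value c >= z_{(1+level)/2}, so the band always
    contains the pointwise Wald CIs.  A non-positive-semidefinite estimated
    correlation is repaired by flooring its eigenvalues at 1e-10 (flagged in
    the result).
    """
    estimates = np.asarray(estimates, dtype=float)
    phi = np.asarray(if_matrix, dtype=float)
    n, K = phi.shape
    if K != len(estimates):
        raise ValueError("if_matrix columns must match estimates")
    cov = (phi.T @ phi) / (n * n)
    corr, repaired = _corr_from_cov(cov)
    c = sup_t_critical(corr, level, draws, seed)
    se = np.sqrt(np.diag(cov))
    return BandResult(
        lower=estimates - c * se, upper=estimates + c * se,
        crit=c, draws=draws, seed=seed, repaired=repaired,
    )
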