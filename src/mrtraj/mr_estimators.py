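"""Two-sample MR estimators for joint (intercept, slope) causal effects.

Given per-SNP exposure effects (gamma, from the first sample) and per-SNP
(intercept, slope) outcome effects with their 2x2 covariance (from the
second-sample mixed models), this module implements:

* per-SNP Wald ratios,
* the naive approach — two separate univariate fixed-effect IVW
  meta-regressions, one for the intercept and one for the slope,
* the multivariate fixed-effects meta-regression, a stacked GLS that
  weights each SNP by the inverse of its full 2x2 covariance and therefore
  also estimates the covariance of the two causal estimates,
* fixed-effects multivariate pooling across cohorts, and
* the joint Wald test of "no effect on intercept and no effect on slope".

Both IVW variants are fixed-effect: the residual variance of the weighted
regression is forced to 1 (no overdispersion or underdispersion scaling),
matching standard two-sample MR practice.  SNP-exposure effects are treated
as fixed and known (no first-stage uncertainty).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mlm_fit import SnpEffectPair

__all__ = [
    "MrEstimate",
    "IvwResult",
    "MrIdentifiabilityError",
    "wald_ratios",
    "ivw_univariate",
    "naive_estimate",
    "mvmr_fixed",
    "pool_cohorts",
    "joint_wald_test",
    "Z_95",
]

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for Wald intervals.
Z_95 = float(stats.norm.ppf(0.975))


class MrIdentifiabilityError(ValueError):
    """No usable instruments remain (all gammas zero or all SNPs excluded)."""


@dataclass(frozen=True)
class MrEstimate:
    """Joint causal-effect estimate of the exposure on intercept and slope.

    ``a_int`` is the exposure->intercept effect (outcome units per exposure
    SD), ``a_slope`` the exposure->slope effect (outcome units/time per
    exposure SD); ``vcov`` is their joint 2x2 covariance.
    """

    a_int: float
    a_slope: float
    vcov: np.ndarray
    method: str
    n_snps_used: int
    excluded_snps: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        vcov = np.asarray(self.vcov, dtype=float)
        if vcov.shape != (2, 2) or not np.allclose(vcov, vcov.T):
            raise ValueError("vcov must be a symmetric 2x2 matrix")
        if np.any(np.diag(vcov) < 0):
            raise ValueError("vcov must have non-negative diagonal")
        object.__setattr__(self, "vcov", vcov)

    @property
    def point(self) -> np.ndarray:
        return np.array([self.a_int, self.a_slope])

    @property
    def se_int(self) -> float:
        return float(np.sqrt(self.vcov[0, 0]))

    @property
    def se_slope(self) -> float:
        return float(np.sqrt(self.vcov[1, 1]))

    @property
    def correlation(self) -> float:
        denom = np.sqrt(self.vcov[0, 0] * self.vcov[1, 1])
        return float(self.vcov[0, 1] / denom) if denom > 0 else 0.0

    @property
    def ci_int(self) -> tuple[float, float]:
        return (self.a_int - Z_95 * self.se_int, self.a_int + Z_95 * self.se_int)

    @property
    def ci_slope(self) -> tuple[float, float]:
        return (
            self.a_slope - Z_95 * self.se_slope,
            self.a_slope + Z_95 * self.se_slope,
        )

    @property
    def p_int(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.a_int) / self.se_int))

    @property
    def p_slope(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.a_slope) / self.se_slope))

    def to_dict(self) -> dict:
        chi2, df, p = joint_wald_test(self)
        return {
            "method": self.method,
            "a_int": self.a_int,
            "a_slope": self.a_slope,
            "se_int": self.se_int,
            "se_slope": self.se_slope,
            "vcov": [float(v) for v in self.vcov.ravel()],
            "correlation": self.correlation,
            "ci_int": list(self.ci_int),
            "ci_slope": list(self.ci_slope),
            "p_int": self.p_int,
            "p_slope": self.p_slope,
            "joint_wald_chi2": chi2,
            "joint_wald_df": df,
            "joint_wald_p": p,
            "n_snps_used": self.n_snps_used,
            "excluded_snps": list(self.excluded_snps),
        }


@dataclass(frozen=True)
class IvwResult:
    """Univariate inverse-variance-weighted meta-regression result."""

    estimate: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - Z_95 * self.se, self.estimate + Z_95 * self.se)

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.estimate) / self.se))


def _usable(gammas: np.ndarray, pairs: list[SnpEffectPair]):
    """Split SNPs into usable and excluded (zero gamma, non-converged,
    or non-positive-definite covariance)."""
    keep, dropped = [], []
    for g, p in zip(gammas, pairs, strict=True):
        if g == 0:
            dropped.append((p.snp_id, "zero gamma"))
        elif not p.usable:
            dropped.append((p.snp_id, "non-converged fit"))
        elif np.linalg.det(p.cov2) <= 0:
            dropped.append((p.snp_id, "singular covariance"))
        else:
            keep.append((float(g), p))
    for snp, why in dropped:
        warnings.warn(f"excluding SNP {snp}: {why}", stacklevel=3)
    return keep, tuple(s for s, _ in dropped)


def wald_ratios(
    gammas: np.ndarray, pairs: list[SnpEffectPair]
) -> list[dict]:
    """Per-SNP Wald ratios b/gamma for intercept and slope.

    First-order standard errors se(b)/|gamma|; SNP-exposure uncertainty is
    ignored (two-sample design, gamma treated as known).
    """
    keep, _ = _usable(np.asarray(gammas, dtype=float), pairs)
    out = []
    for g, p in keep:
        out.append(
            {
                "snp_id": p.snp_id,
                "ratio_int": p.b_int / g,
                "se_int": p.se_int / abs(g),
                "ratio_slope": p.b_slope / g,
                "se_slope": p.se_slope / abs(g),
            }
        )
    return out


def ivw_univariate(
    gammas: np.ndarray, effects: np.ndarray, ses: np.ndarray
) -> IvwResult:
    """Fixed-effect IVW: weighted no-intercept regression of SNP-outcome
    effects on SNP-exposure effects, weights 1/se^2, residual variance
    forced to 1."""
    g = np.asarray(gammas, dtype=float)
    b = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    mask = g != 0
    if not mask.any():
        raise MrIdentifiabilityError("all SNP-exposure effects are zero")
    g, b, s = g[mask], b[mask], s[mask]
    w = 1.0 / s**2
    denom = float(np.sum(w * g**2))
    est = float(np.sum(w * g * b)) / denom
    return IvwResult(estimate=est, se=1.0 / np.sqrt(denom))


def naive_estimate(gammas: np.ndarray, pairs: list[SnpEffectPair]) -> MrEstimate:
    """Naive approach: two separate univariate IVW meta-regressions.

    The intercept and slope effects are estimated independently; the
    covariance between them is ignored (off-diagonal of ``vcov`` is 0).
    """
    keep, excluded = _usable(np.asarray(gammas, dtype=float), pairs)
    if not keep:
        raise MrIdentifiabilityError("no usable SNPs for the naive estimator")
    g = np.array([gk for gk, _ in keep])
    b_int = np.array([p.b_int for _, p in keep])
    b_slope = np.array([p.b_slope for _, p in keep])
    se_int = np.array([p.se_int for _, p in keep])
    se_slope = np.array([p.se_slope for _, p in keep])
    r_int = ivw_univariate(g, b_int, se_int)
    r_slope = ivw_univariate(g, b_slope, se_slope)
    return MrEstimate(
        a_int=r_int.estimate,
        a_slope=r_slope.estimate,
        vcov=np.diag([r_int.se**2, r_slope.se**2]),
        method="naive",
        n_snps_used=len(keep),
        excluded_snps=excluded,
    )


def mvmr_fixed(gammas: np.ndarray, pairs: list[SnpEffectPair]) -> MrEstimate:
    """Multivariate fixed-effects meta-regression of (intercept, slope) pairs.

    Stacked GLS: with response beta_k = (b_int, b_slope)', design
    X_k = gamma_k * I2 and weight S_k^{-1} = cov2_k^{-1},

        a_hat = (sum X_k' S_k^-1 X_k)^-1 (sum X_k' S_k^-1 beta_k),
        vcov(a_hat) = (sum X_k' S_k^-1 X_k)^-1.

    No dispersion scaling is applied (residual variance forced to 1).
    """
    keep, excluded = _usable(np.asarray(gammas, dtype=float), pairs)
    if not keep:
        raise MrIdentifiabilityError("no usable SNPs for the multivariate estimator")
    A = np.zeros((2, 2))
    rhs = np.zeros(2)
    for g, p in keep:
        Sinv = np.linalg.inv(p.cov2)
        A += g * g * Sinv
        rhs += g * (Sinv @ np.array([p.b_int, p.b_slope]))
    vcov = np.linalg.inv(A)
    vcov = 0.5 * (vcov + vcov.T)
    a = vcov @ rhs
    return MrEstimate(
        a_int=float(a[0]),
        a_slope=float(a[1]),
        vcov=vcov,
        method="multivariate",
        n_snps_used=len(keep),
        excluded_snps=excluded,
    )


def pool_cohorts(estimates: list[MrEstimate]) -> MrEstimate:
    """Fixed-effects multivariate pooling of cohort-level estimates.

    Precision weighting with the full 2x2 covariances:
    vcov_pooled = (sum V_j^-1)^-1 and
    a_pooled = vcov_pooled * sum V_j^-1 a_j.
    """
    if not estimates:
        raise ValueError("need at least one estimate to pool")
    A = np.zeros((2, 2))
    rhs = np.zeros(2)
    for j, est in enumerate(estimates):
        if np.linalg.det(est.vcov) <= 0:
            raise np.linalg.LinAlgError(f"singular vcov for cohort {j}")
        Vinv = np.linalg.inv(est.vcov)
        A += Vinv
        rhs += Vinv @ est.point
    vcov = np.linalg.inv(A)
    vcov = 0.5 * (vcov + vcov.T)
    a = vcov @ rhs
    methods = {e.method for e in estimates}
    return MrEstimate(
        a_int=float(a[0]),
        a_slope=float(a[1]),
        vcov=vcov,
        method=methods.pop() if len(methods) == 1 else "pooled",
        n_snps_used=sum(e.n_snps_used for e in estimates),
    )


def joint_wald_test(est: MrEstimate) -> tuple[float, int, float]:
    """Joint chi-square test that both causal effects are zero.

    chi2 = a' V^-1 a on 2 degrees of freedom: a single test of whether the
    exposure has any effect on progression.
    """
    if np.linalg.det(est.vcov) <= 0:
        raise np.linalg.LinAlgError("vcov is singular")
    a = est.point
    chi2 = float(a @ np.linalg.solve(est.vcov, a))
    return chi2, 2, float(stats.chi2.sf(chi2, df=2))
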