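"""Per-SNP linear mixed models for longitudinal progression outcomes.

For each SNP k the model is

    y_ij = b0 + u0i + b1*G_ik + (b2 + u1i + b3*G_ik)*t_ij + e_ij,

with fixed design columns (1, G, t, G*t), random design (1, t), random
effects (u0i, u1i) ~ N(0, Psi) and residuals e_ij ~ N(0, sigma^2).  The MR
stage needs the SNP-intercept effect b1, the SNP-slope effect b3 and their
joint 2x2 covariance, per SNP.

Estimation is maximum likelihood (REML behind a flag) on the profiled
deviance: writing the marginal covariance of individual i as
sigma^2 * (Z_i Lambda Z_i' + I) with Lambda = Psi/sigma^2, both the fixed
effects and sigma^2 have closed-form profiles, leaving a 3-parameter
optimisation over the log-Cholesky factor of Lambda.  Because a simulation
study refits this model tens of thousands of times, the likelihood is
evaluated on a pre-grouped workspace: individuals sharing a visit-time
pattern share one covariance factorisation (one factorisation total for a
balanced cohort), and irregular patterns are batched by visit count with
stacked linear algebra.  Fits across SNPs on the same cohort reuse the
workspace and warm-start the variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .cohort_sim import GenotypeMatrix, LongitudinalData

__all__ = [
    "LmmFit",
    "SnpEffectPair",
    "IdentifiabilityError",
    "AllSnpsFailedError",
    "LmmWorkspace",
    "fit_lmm",
    "snp_effects",
    "fit_all_snps",
    "gls_fixed_effects",
]

logger = logging.getLogger(__name__)

#: Fixed-effect column order used throughout.
FIXED_NAMES = ("intercept", "dosage", "time", "dosage_time")
# Internal evaluation uses ordering (1, t, dosage, dosage*t); this permutation
# converts to the public (1, dosage, t, dosage*t) order.
_PERM = np.array([0, 2, 1, 3])

_LOG2PI = np.log(2.0 * np.pi)

#: Relative log-likelihood tolerance and iteration cap of the optimiser.
REL_TOL = 1e-8
MAX_ITER = 200


class IdentifiabilityError(ValueError):
    """The fixed design is singular (e.g. dosage constant across individuals)."""


class AllSnpsFailedError(RuntimeError):
    """Every per-SNP mixed-model fit failed to converge."""


@dataclass(frozen=True)
class LmmFit:
    """Result of one per-SNP mixed-model fit.

    ``fixed`` is ordered (intercept, dosage, time, dosage x time); the
    SNP-intercept effect is ``fixed[1]`` and the SNP-slope effect ``fixed[3]``.
    ``psi`` is the fitted random-effects covariance and ``sigma2`` the level-1
    residual variance.
    """

    fixed: np.ndarray
    fixed_vcov: np.ndarray
    psi: np.ndarray
    sigma2: float
    loglik: float
    converged: bool
    n_individuals: int
    n_records: int
    method: str = "ML"
    n_iter: int = 0

    @property
    def var_components(self) -> tuple[float, float, float, float]:
        """(sigma0^2, sigma01, sigma1^2, sigma^2)."""
        return (
            float(self.psi[0, 0]),
            float(self.psi[0, 1]),
            float(self.psi[1, 1]),
            float(self.sigma2),
        )


@dataclass(frozen=True)
class SnpEffectPair:
    """Estimated (SNP-intercept, SNP-slope) effects with their 2x2 covariance.

    This is the "second sample" summary statistic of the two-sample design:
    one pair per SNP, carried into the meta-regression stage.
    """

    snp_id: str
    b_int: float
    b_slope: float
    cov2: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        cov2 = np.asarray(self.cov2, dtype=float)
        if cov2.shape != (2, 2):
            raise ValueError("cov2 must be 2x2")
        if not np.allclose(cov2, cov2.T):
            raise ValueError("cov2 must be symmetric")
        object.__setattr__(self, "cov2", cov2)

    @property
    def usable(self) -> bool:
        return bool(self.converged and np.all(np.diag(self.cov2) > 0))

    @property
    def se_int(self) -> float:
        return float(np.sqrt(self.cov2[0, 0]))

    @property
    def se_slope(self) -> float:
        return float(np.sqrt(self.cov2[1, 1]))

    @property
    def correlation(self) -> float:
        return float(self.cov2[0, 1] / np.sqrt(self.cov2[0, 0] * self.cov2[1, 1]))


class LmmWorkspace:
    """Pre-reduced cohort data for repeated per-SNP mixed-model fits.

    The random design Z_i = (1, t_ij) has rank 2, so by the Woodbury
    identity every per-individual GLS quantity reduces to the 2x2
    cross-products C_i = Z_i'Z_i, h_i = Z_i'y_i and the scalar s_i = y_i'y_i,
    all independent of the variance parameters: with Lambda = Psi/sigma^2 and
    K_i = I + L' C_i L (L the Cholesky factor of Lambda),

        Z_i' V_i^-1 Z_i = C_i - C_i L K_i^-1 L' C_i,
        Z_i' V_i^-1 y_i = h_i - C_i L K_i^-1 L' h_i,
        y_i' V_i^-1 y_i = s_i - h_i' L K_i^-1 L' h_i,
        log det V_i     = log det K_i.

    The cross-products are computed once at construction; each likelihood
    evaluation is a handful of batched 2x2 operations across individuals,
    with cost independent of the number of visits per individual.
    """

    def __init__(self, data: LongitudinalData):
        rec = data.records
        ids = rec["id"].to_numpy()
        order = np.argsort(ids, kind="stable")
        ids = ids[order]
        times = rec["time"].to_numpy(dtype=float)[order]
        y = rec["y"].to_numpy(dtype=float)[order]
        uniq, inverse, counts = np.unique(ids, return_inverse=True, return_counts=True)
        self.individual_ids = uniq
        self.n_individuals = len(uniq)
        self.n_records = len(ids)
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if not np.any(counts >= 2):
            raise IdentifiabilityError(
                "random slope unidentifiable: no individual has >= 2 visits"
            )
        n = self.n_individuals
        # per-individual cross-products via scatter-adds; components of
        # C_i = [[a, b], [b, c]], h_i = (h0, h1), s_i
        self._a = np.bincount(inverse, minlength=n).astype(float)
        self._b = np.bincount(inverse, weights=times, minlength=n)
        self._c = np.bincount(inverse, weights=times**2, minlength=n)
        self._h0 = np.bincount(inverse, weights=y, minlength=n)
        self._h1 = np.bincount(inverse, weights=times * y, minlength=n)
        self._s = np.bincount(inverse, weights=y**2, minlength=n)

    # -- likelihood machinery ------------------------------------------------

    @staticmethod
    def _lam_chol(theta: np.ndarray) -> np.ndarray:
        """Log-Cholesky parameterisation of Lambda = Psi / sigma^2."""
        return np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])

    def _per_individual(self, lam_chol: np.ndarray):
        """Woodbury-reduced per-individual GLS statistics, expanded into
        component-wise operations on flat arrays (everything is 2x2)."""
        a, b, c = self._a, self._b, self._c
        h0, h1, s = self._h0, self._h1, self._s
        l0, l1, l2 = lam_chol[0, 0], lam_chol[1, 0], lam_chol[1, 1]
        # T = C L ; K = I + L' T
        t00 = a * l0 + b * l1
        t01 = b * l2
        t10 = b * l0 + c * l1
        t11 = c * l2
        k00 = l0 * t00 + l1 * t10 + 1.0
        k01 = l0 * t01 + l1 * t11
        k10 = l2 * t10
        k11 = l2 * t11 + 1.0
        detK = k00 * k11 - k01 * k10
        logdet = float(np.sum(np.log(detK)))
        # D = L K^-1 L'
        inv = 1.0 / detK
        ki00, ki01, ki10, ki11 = k11 * inv, -k01 * inv, -k10 * inv, k00 * inv
        p00 = l0 * ki00
        p01 = l0 * ki01
        p10 = l1 * ki00 + l2 * ki10
        p11 = l1 * ki01 + l2 * ki11
        d00 = p00 * l0
        d01 = p00 * l1 + p01 * l2
        d10 = p10 * l0
        d11 = p10 * l1 + p11 * l2
        # CD = C D ; M = C - CD C ; w = h - CD h ; q = s - h' D h
        cd00 = a * d00 + b * d10
        cd01 = a * d01 + b * d11
        cd10 = b * d00 + c * d10
        cd11 = b * d01 + c * d11
        m00 = a - (cd00 * a + cd01 * b)
        m01 = b - (cd00 * b + cd01 * c)
        m11 = c - (cd10 * b + cd11 * c)
        w0 = h0 - (cd00 * h0 + cd01 * h1)
        w1 = h1 - (cd10 * h0 + cd11 * h1)
        q = s - (d00 * h0 * h0 + (d01 + d10) * h0 * h1 + d11 * h1 * h1)
        return (m00, m01, m11), (w0, w1), q, logdet

    def _normal_equations(self, lam_chol: np.ndarray, g: np.ndarray):
        """Accumulate GLS cross-products in (1, t | g, g*t) block order."""
        (m00, m01, m11), (w0, w1), q, logdet = self._per_individual(lam_chol)
        g2 = g * g
        SM0 = np.array([[m00.sum(), m01.sum()], [m01.sum(), m11.sum()]])
        SM1 = np.array([[g @ m00, g @ m01], [g @ m01, g @ m11]])
        SM2 = np.array([[g2 @ m00, g2 @ m01], [g2 @ m01, g2 @ m11]])
        Sw0 = np.array([w0.sum(), w1.sum()])
        Sw1 = np.array([g @ w0, g @ w1])
        ytVy = float(q.sum())
        XtVX = np.block([[SM0, SM1], [SM1, SM2]])
        XtVy = np.concatenate([Sw0, Sw1])
        return XtVX, XtVy, ytVy, logdet

    def profiled_deviance(
        self, theta: np.ndarray, g: np.ndarray, reml: bool = False
    ) -> float:
        """-2 log-likelihood profiled over fixed effects and sigma^2."""
        lam_chol = self._lam_chol(theta)
        XtVX, XtVy, ytVy, logdet = self._normal_equations(lam_chol, g)
        try:
            beta = linalg.solve(XtVX, XtVy, assume_a="pos")
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytVy - beta @ XtVy
        if rss <= 0:
            return np.inf
        N, p = self.n_records, 4
        if reml:
            sigma2 = rss / (N - p)
            sign, ld_x = np.linalg.slogdet(XtVX)
            return (N - p) * (_LOG2PI + np.log(sigma2) + 1.0) + logdet + ld_x
        sigma2 = rss / N
        return N * (_LOG2PI + np.log(sigma2) + 1.0) + logdet

    def _solution_at(self, theta: np.ndarray, g: np.ndarray, reml: bool):
        lam_chol = self._lam_chol(theta)
        XtVX, XtVy, ytVy, logdet = self._normal_equations(lam_chol, g)
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
        rss = ytVy - beta @ XtVy
        denom = self.n_records - 4 if reml else self.n_records
        sigma2 = float(rss / denom)
        vcov = sigma2 * linalg.inv(XtVX)
        psi = sigma2 * (lam_chol @ lam_chol.T)
        dev = self.profiled_deviance(theta, g, reml=reml)
        return (
            beta[_PERM],
            vcov[np.ix_(_PERM, _PERM)],
            psi,
            sigma2,
            -0.5 * dev,
        )

    def default_start(self) -> np.ndarray:
        """Generic cold start: random-intercept variance equal to the
        residual variance, random-slope variance 1/16 of it, no covariance."""
        return np.array([0.0, 0.0, np.log(0.25)])

    def fit(
        self,
        dosage: np.ndarray,
        theta0: np.ndarray | None = None,
        reml: bool = False,
    ) -> tuple[LmmFit, np.ndarray]:
        """Fit the model for one dosage vector; returns the fit and the
        optimal variance parameters (for warm-starting the next SNP)."""
        g = np.asarray(dosage, dtype=float)
        if g.shape != (self.n_individuals,):
            raise ValueError("dosage must have one entry per individual")
        if np.ptp(g) == 0:
            raise IdentifiabilityError("dosage is constant across individuals")
        if theta0 is None:
            theta0 = self.default_start()
        f0 = self.profiled_deviance(theta0, g, reml=reml)
        res = optimize.minimize(
            self.profiled_deviance,
            theta0,
            args=(g, reml),
            method="Nelder-Mead",
            options={
                "xatol": 1e-4,
                "fatol": REL_TOL * max(1.0, abs(f0)),
                "maxiter": MAX_ITER,
                "maxfev": 4 * MAX_ITER,
            },
        )
        beta, vcov, psi, sigma2, loglik = self._solution_at(res.x, g, reml)
        fit = LmmFit(
            fixed=beta,
            fixed_vcov=vcov,
            psi=psi,
            sigma2=sigma2,
            loglik=loglik,
            converged=bool(res.success),
            n_individuals=self.n_individuals,
            n_records=self.n_records,
            method="REML" if reml else "ML",
            n_iter=int(res.nit),
        )
        return fit, res.x


def fit_lmm(data: LongitudinalData, dosage: np.ndarray, reml: bool = False) -> LmmFit:
    """Fit the random-intercept/random-slope model for a single SNP.

    ``dosage`` must hold one allele count per individual, aligned with the
    individuals in ascending id order (the order of ``data.covariates``).
    """
    ws = LmmWorkspace(data)
    fit, _ = ws.fit(np.asarray(dosage, dtype=float), reml=reml)
    return fit


def snp_effects(fit: LmmFit, snp_id: str) -> SnpEffectPair:
    """Extract the (SNP-intercept, SNP-slope) pair and its covariance block."""
    sl = np.ix_([1, 3], [1, 3])
    return SnpEffectPair(
        snp_id=str(snp_id),
        b_int=float(fit.fixed[1]),
        b_slope=float(fit.fixed[3]),
        cov2=fit.fixed_vcov[sl],
        converged=fit.converged,
    )


def fit_all_snps(
    data: LongitudinalData, G: GenotypeMatrix, reml: bool = False
) -> list[SnpEffectPair]:
    """Fit one mixed model per SNP and collect the effect pairs.

    Rows of ``G`` must align with the individuals of ``data``.  Fits are
    warm-started from the previous SNP's variance components (the SNP explains
    a tiny share of variance, so components barely move between SNPs).
    Non-converged SNPs are returned flagged; the MR stage excludes them.
    """
    ws = LmmWorkspace(data)
    if G.n_individuals != ws.n_individuals:
        raise ValueError("genotype rows do not match the number of individuals")
    pairs: list[SnpEffectPair] = []
    theta = None
    n_failed = 0
    for k in range(G.n_snps):
        fit, theta_opt = ws.fit(G.values[:, k].astype(float), theta0=theta, reml=reml)
        if fit.converged:
            theta = theta_opt
        else:
            n_failed += 1
        pairs.append(snp_effects(fit, G.snp_ids[k]))
    if n_failed:
        logger.warning("%d of %d per-SNP fits did not converge", n_failed, G.n_snps)
    if n_failed == G.n_snps:
        raise AllSnpsFailedError("no per-SNP mixed model converged")
    return pairs


def gls_fixed_effects(
    data: LongitudinalData,
    dosage: np.ndarray,
    re_cov: np.ndarray,
    resid_var: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized-least-squares fixed effects at known variance components.

    Returns (beta, vcov) in the (intercept, dosage, time, dosage x time)
    order.  Useful for oracle comparisons and for fitting with variance
    components held at their generating values.
    """
    ws = LmmWorkspace(data)
    g = np.asarray(dosage, dtype=float)
    lam = np.asarray(re_cov, dtype=float) / float(resid_var)
    lam_chol = np.linalg.cholesky(lam)
    XtVX, XtVy, _, _ = ws._normal_equations(lam_chol, g)
    beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    vcov = float(resid_var) * linalg.inv(XtVX)
    return beta[_PERM], vcov[np.ix_(_PERM, _PERM)]


def effects_to_frame(pairs: list[SnpEffectPair]) -> pd.DataFrame:
    """Per-SNP effects as the TSV interchange schema."""
    return pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in pairs],
            "b_int": [p.b_int for p in pairs],
            "se_int": [p.se_int for p in pairs],
            "b_slope": [p.b_slope for p in pairs],
            "se_slope": [p.se_slope for p in pairs],
            "cov_int_slope": [float(p.cov2[0, 1]) for p in pairs],
            "converged": [p.converged for p in pairs],
        }
    )


def effects_from_frame(df: pd.DataFrame) -> list[SnpEffectPair]:
    """Inverse of :func:`effects_to_frame`."""
    pairs = []
    for row in df.itertuples(index=False):
        cov2 = np.array(
            [
                [row.se_int**2, row.cov_int_slope],
                [row.cov_int_slope, row.se_slope**2],
            ]
        )
        pairs.append(
            SnpEffectPair(
                snp_id=str(row.snp_id),
                b_int=float(row.b_int),
                b_slope=float(row.b_slope),
                cov2=cov2,
                converged=bool(row.converged),
            )
        )
    return pairs
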