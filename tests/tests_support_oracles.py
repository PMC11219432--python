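"""Brute-force oracles shared by the acceptance checks.

Each function returns a discrepancy between the package implementation and an
independent direct computation (explicit block-matrix construction and
inversion), so the calling test asserts only on a magnitude.
"""

import numpy as np
import scipy.linalg as sla

from mrtraj.mlm_fit import SnpEffectPair, gls_fixed_effects
from mrtraj.mr_estimators import mvmr_fixed, naive_estimate


def _random_inputs(seed: int, k: int, correlated: bool = True):
    rng = np.random.default_rng(seed)
    gammas, pairs = [], []
    for i in range(k):
        g = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
        a = rng.uniform(0.1, 0.5)
        d = rng.uniform(0.05, 0.3)
        r = rng.uniform(-0.8, 0.8) if correlated else 0.0
        cov2 = np.array([[a**2, r * a * d], [r * a * d, d**2]])
        pairs.append(
            SnpEffectPair(
                snp_id=f"s{i}",
                b_int=float(rng.normal(0, 1)),
                b_slope=float(rng.normal(0, 0.3)),
                cov2=cov2,
            )
        )
        gammas.append(g)
    return np.array(gammas), pairs


def diagonal_equality_check(seed: int, k: int) -> float:
    """Max |multivariate - naive| over point estimates and SEs when all
    per-SNP covariances are diagonal (block-diagonal GLS decouples)."""
    gammas, pairs = _random_inputs(seed, k, correlated=False)
    mv = mvmr_fixed(gammas, pairs)
    nv = naive_estimate(gammas, pairs)
    return max(
        abs(mv.a_int - nv.a_int),
        abs(mv.a_slope - nv.a_slope),
        abs(mv.se_int - nv.se_int),
        abs(mv.se_slope - nv.se_slope),
    )


def stacked_gls_discrepancy(seed: int, k: int) -> float:
    """Max deviation of the multivariate estimator from an explicit
    2K x 2K weight-matrix GLS."""
    gammas, pairs = _random_inputs(seed, k)
    mv = mvmr_fixed(gammas, pairs)
    beta = np.concatenate([[p.b_int, p.b_slope] for p in pairs])
    X = np.vstack([g * np.eye(2) for g in gammas])
    W = np.linalg.inv(sla.block_diag(*[p.cov2 for p in pairs]))
    vcov = np.linalg.inv(X.T @ W @ X)
    est = vcov @ (X.T @ W @ beta)
    return max(
        float(np.max(np.abs(mv.point - est))),
        float(np.max(np.abs(mv.vcov - vcov))),
    )


def lmm_gls_discrepancy(seed: int) -> float:
    """Max deviation of the workspace GLS (variance components held at
    truth) from a dense block-diagonal GLS on simulated balanced data."""
    import pandas as pd

    from mrtraj.cohort_sim import LongitudinalData

    rng = np.random.default_rng(seed)
    n, times = 50, np.arange(7.0)
    re_cov = np.array([[4.0, -0.5], [-0.5, 1.0]])
    resid_var = 2.0
    g = rng.binomial(2, 0.4, size=n).astype(float)
    u = rng.multivariate_normal([0, 0], re_cov, size=n)
    rows = []
    for i in range(n):
        eps = rng.normal(0, np.sqrt(resid_var), size=len(times))
        y = (10 + u[i, 0] + 0.5 * g[i]) + (1 + u[i, 1] + 0.2 * g[i]) * times + eps
        rows.append(pd.DataFrame({"id": i, "time": times, "y": y}))
    data = LongitudinalData(
        records=pd.concat(rows, ignore_index=True),
        covariates=pd.DataFrame({"id": np.arange(n), "x": 0.0, "c": 0.0}),
    )
    beta, vcov = gls_fixed_effects(data, g, re_cov, resid_var)
    rec = data.records
    ids = rec["id"].to_numpy()
    t = rec["time"].to_numpy()
    y = rec["y"].to_numpy()
    X = np.column_stack([np.ones_like(t), g[ids], t, g[ids] * t])
    blocks = []
    for i in np.unique(ids):
        m = ids == i
        Zi = np.column_stack([np.ones(m.sum()), t[m]])
        blocks.append(Zi @ re_cov @ Zi.T + resid_var * np.eye(m.sum()))
    Vinv = np.linalg.inv(sla.block_diag(*blocks))
    vcov_o = np.linalg.inv(X.T @ Vinv @ X)
    beta_o = vcov_o @ (X.T @ Vinv @ y)
    return max(
        float(np.max(np.abs(beta - beta_o))),
        float(np.max(np.abs(vcov - vcov_o))),
    )
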