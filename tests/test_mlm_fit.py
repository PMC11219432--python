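import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

from mrtraj.cohort_sim import (
    BalancedSchedule,
    LongitudinalData,
    ScenarioConfig,
    simulate_trajectories,
    simulate_visit_schedule,
)
from mrtraj.mlm_fit import (
    IdentifiabilityError,
    LmmFit,
    effects_from_frame,
    effects_to_frame,
    fit_all_snps,
    fit_lmm,
    gls_fixed_effects,
    snp_effects,
)


def _dense_gls_oracle(records, g, re_cov, resid_var):
    """Brute-force GLS: build the full block-diagonal covariance and invert."""
    ids = records["id"].to_numpy()
    t = records["time"].to_numpy()
    y = records["y"].to_numpy()
    X = np.column_stack([np.ones_like(t), g[ids], t, g[ids] * t])
    blocks = []
    for i in np.unique(ids):
        m = ids == i
        Zi = np.column_stack([np.ones(m.sum()), t[m]])
        blocks.append(Zi @ re_cov @ Zi.T + resid_var * np.eye(m.sum()))
    Vinv = np.linalg.inv(sla.block_diag(*blocks))
    vcov = np.linalg.inv(X.T @ Vinv @ X)
    beta = vcov @ (X.T @ Vinv @ y)
    return beta, vcov


def _simulate_single_snp(n, re_cov, resid_var, b_int, b_slope, seed, times=None):
    """Direct per-SNP data: y = 10 + b_int*g + (1 + b_slope*g)*t + noise."""
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.4, size=n).astype(float)
    if times is None:
        times = np.arange(7.0)
    u = rng.multivariate_normal([0, 0], re_cov, size=n)
    rows = []
    for i in range(n):
        eps = rng.normal(0, np.sqrt(resid_var), size=len(times))
        y = (10 + u[i, 0] + b_int * g[i]) + (1 + u[i, 1] + b_slope * g[i]) * times + eps
        rows.append(pd.DataFrame({"id": i, "time": times, "y": y}))
    data = LongitudinalData(
        records=pd.concat(rows, ignore_index=True),
        covariates=pd.DataFrame({"id": np.arange(n), "x": 0.0, "c": 0.0}),
    )
    return data, g


class TestFitLmm:
    def test_near_noiseless_recovery(self):
        data, g = _simulate_single_snp(
            40, np.eye(2) * 1e-8, 1e-8, b_int=0.5, b_slope=0.2, seed=0
        )
        fit = fit_lmm(data, g)
        assert fit.fixed[1] == pytest.approx(0.5, abs=1e-4)
        assert fit.fixed[3] == pytest.approx(0.2, abs=1e-4)

    def test_gls_oracle_at_true_variance_components(self):
        re_cov = np.array([[4.0, -0.5], [-0.5, 1.0]])
        data, g = _simulate_single_snp(50, re_cov, 2.0, 0.5, 0.2, seed=1)
        beta, vcov = gls_fixed_effects(data, g, re_cov, 2.0)
        beta_o, vcov_o = _dense_gls_oracle(data.records, g, re_cov, 2.0)
        np.testing.assert_allclose(beta, beta_o, atol=1e-6)
        np.testing.assert_allclose(vcov, vcov_o, atol=1e-6)

    def test_gls_oracle_unbalanced(self, unbalanced_cohort):
        data = unbalanced_cohort.data
        g = unbalanced_cohort.genotypes.values[:, 0].astype(float)
        cfg = unbalanced_cohort.config
        beta, vcov = gls_fixed_effects(data, g, cfg.re_cov, cfg.resid_var)
        beta_o, vcov_o = _dense_gls_oracle(data.records, g, cfg.re_cov, cfg.resid_var)
        np.testing.assert_allclose(beta, beta_o, atol=1e-6)
        np.testing.assert_allclose(vcov, vcov_o, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self, small_cohort):
        """Independent-route check: statsmodels MixedLM (ML) on the same data."""
        smf = pytest.importorskip("statsmodels.formula.api")
        g = small_cohort.genotypes.values[:, 0].astype(float)
        fit = fit_lmm(small_cohort.data, g)
        df = small_cohort.data.records.copy()
        df["g"] = g[df["id"].to_numpy()]
        m = smf.mixedlm("y ~ g * time", df, groups=df["id"], re_formula="~time").fit(
            reml=False
        )
        # statsmodels order: Intercept, g, time, g:time — same as ours
        np.testing.assert_allclose(fit.fixed, m.fe_params.values, atol=1e-5)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.fixed_vcov)), m.bse_fe.values, rtol=1e-3
        )
        assert fit.loglik == pytest.approx(m.llf, abs=1e-4)

    def test_parameter_recovery_single_snp(self, small_cohort):
        """(b1k, b3k) lies within 3 model SEs of (alpha1*gamma_std,
        alpha4*gamma_std): the proportionality that MR exploits."""
        cfg = small_cohort.config
        k = 0
        gamma_std = small_cohort.scaling.gamma_std[k]
        fit = fit_lmm(small_cohort.data, small_cohort.genotypes.values[:, k].astype(float))
        se = np.sqrt(np.diag(fit.fixed_vcov))
        assert abs(fit.fixed[1] - cfg.alpha1 * gamma_std) < 3 * se[1]
        assert abs(fit.fixed[3] - cfg.alpha4 * gamma_std) < 3 * se[3]

    def test_time_rescaling_equivariance(self, small_cohort):
        g = small_cohort.genotypes.values[:, 1].astype(float)
        fit = fit_lmm(small_cohort.data, g)
        scaled = small_cohort.data.records.copy()
        scaled["time"] = scaled["time"] * 2.0
        data2 = LongitudinalData(
            records=scaled, covariates=small_cohort.data.covariates
        )
        fit2 = fit_lmm(data2, g)
        assert fit2.fixed[1] == pytest.approx(fit.fixed[1], abs=1e-3)
        assert fit2.fixed[3] == pytest.approx(fit.fixed[3] / 2.0, abs=1e-3)

    def test_reml_close_to_ml_and_flagged(self, small_cohort):
        g = small_cohort.genotypes.values[:, 2].astype(float)
        ml = fit_lmm(small_cohort.data, g)
        reml = fit_lmm(small_cohort.data, g, reml=True)
        assert reml.method == "REML"
        np.testing.assert_allclose(reml.fixed, ml.fixed, atol=0.02)
        # REML variance components are no smaller than ML ones on average
        assert reml.sigma2 == pytest.approx(ml.sigma2, rel=0.05)

    def test_constant_dosage_raises(self, small_cohort):
        with pytest.raises(IdentifiabilityError):
            fit_lmm(small_cohort.data, np.ones(small_cohort.config.n_individuals))

    def test_all_single_visits_raises(self):
        data = LongitudinalData(
            records=pd.DataFrame(
                {"id": [0, 1, 2], "time": [0.0, 1.0, 2.0], "y": [1.0, 2.0, 3.0]}
            ),
            covariates=pd.DataFrame({"id": [0, 1, 2], "x": 0.0, "c": 0.0}),
        )
        with pytest.raises(IdentifiabilityError):
            fit_lmm(data, np.array([0.0, 1.0, 2.0]))


class TestSnpEffects:
    def test_block_extraction(self):
        vcov = np.diag([1.0, 2.0, 3.0, 4.0]).astype(float)
        vcov[1, 3] = vcov[3, 1] = -0.3
        fit = LmmFit(
            fixed=np.array([1.0, 0.5, 2.0, 0.1]),
            fixed_vcov=vcov,
            psi=np.eye(2),
            sigma2=1.0,
            loglik=0.0,
            converged=True,
            n_individuals=10,
            n_records=70,
        )
        pair = snp_effects(fit, "rs9")
        assert pair.b_int == 0.5 and pair.b_slope == 0.1
        np.testing.assert_allclose(pair.cov2, [[2.0, -0.3], [-0.3, 4.0]])

    def test_non_converged_flag_propagates(self):
        fit = LmmFit(
            fixed=np.zeros(4),
            fixed_vcov=np.eye(4),
            psi=np.eye(2),
            sigma2=1.0,
            loglik=0.0,
            converged=False,
            n_individuals=10,
            n_records=70,
        )
        pair = snp_effects(fit, "rs1")
        assert not pair.usable


class TestFitAllSnps:
    def test_one_pair_per_snp_in_column_order(self, small_cohort):
        pairs = fit_all_snps(small_cohort.data, small_cohort.genotypes)
        assert [p.snp_id for p in pairs] == list(small_cohort.genotypes.snp_ids)

    def test_duplicate_column_gives_identical_pair(self, small_cohort):
        from mrtraj.cohort_sim import GenotypeMatrix

        g = small_cohort.genotypes.values[:, 0].astype(float)
        # the fit itself is deterministic: refitting the same dosage from the
        # same start reproduces the result bit for bit
        a = fit_lmm(small_cohort.data, g)
        b = fit_lmm(small_cohort.data, g)
        np.testing.assert_array_equal(a.fixed, b.fixed)
        np.testing.assert_array_equal(a.fixed_vcov, b.fixed_vcov)
        # within fit_all_snps the second copy is warm-started, so it agrees
        # to optimiser tolerance rather than bitwise
        v = small_cohort.genotypes.values[:, [0, 0]]
        G = GenotypeMatrix(values=v, snp_ids=np.array(["a", "b"], dtype=object))
        pairs = fit_all_snps(small_cohort.data, G)
        assert pairs[0].b_int == pytest.approx(pairs[1].b_int, rel=1e-4)
        np.testing.assert_allclose(pairs[0].cov2, pairs[1].cov2, rtol=2e-3)

    def test_negative_random_covariance_gives_negative_correlation(self, small_cohort):
        """sigma01 = -6.0 in the generator propagates into a negative
        correlation between the per-SNP intercept and slope effects."""
        pairs = fit_all_snps(small_cohort.data, small_cohort.genotypes)
        assert np.mean([p.correlation for p in pairs]) < 0

    def test_effects_frame_round_trip(self, small_cohort):
        pairs = fit_all_snps(small_cohort.data, small_cohort.genotypes)
        again = effects_from_frame(effects_to_frame(pairs))
        for a, b in zip(pairs, again):
            assert a.snp_id == b.snp_id
            assert a.b_int == pytest.approx(b.b_int)
            np.testing.assert_allclose(a.cov2, b.cov2, rtol=1e-12)


class TestSeCalibration:
    def test_empirical_sd_matches_mean_model_se(self):
        """Across simulation replicates, the spread of (b1k, b3k) should match
        the model-based SEs (the fixed-effect covariance is trustworthy)."""
        re_cov = np.array([[4.0, -0.5], [-0.5, 1.0]])
        ests, ses = [], []
        for rep in range(40):
            data, g = _simulate_single_snp(60, re_cov, 2.0, 0.5, 0.2, seed=100 + rep)
            fit = fit_lmm(data, g)
            ests.append([fit.fixed[1], fit.fixed[3]])
            ses.append(np.sqrt(np.diag(fit.fixed_vcov))[[1, 3]])
        emp_sd = np.std(np.array(ests), axis=0, ddof=1)
        mean_se = np.mean(np.array(ses), axis=0)
        # 40 replicates: SD of an SD estimate is ~11%
        np.testing.assert_allclose(emp_sd, mean_se, rtol=0.35)
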