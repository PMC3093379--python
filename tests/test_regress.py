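"""Regression fits: exact identities, independent sandwich/optimizer oracles,
equivariance, and scan behavior."""

import numpy as np
import pytest
from scipy import optimize, stats

from gxescan import (Cohort, GxescanError, NotSupportedError, ScenarioConfig,
                     fit_cox_gxe, fit_linear_gxe, fit_logistic_gxe,
                     genome_scan, joint_wald_test, lrt_test, simulate_cohort,
                     wald_test)
from gxescan.regress import GxEFit, _linear_scan_batch


from _oracles import (cox_partial_loglik_bruteforce,
                      cox_sandwich_bruteforce, logistic_nll,
                      ols_sandwich_bruteforce)

_ols_sandwich_bruteforce = ols_sandwich_bruteforce
_logistic_nll = logistic_nll
_cox_partial_loglik_bruteforce = cox_partial_loglik_bruteforce
_cox_sandwich_bruteforce = cox_sandwich_bruteforce


# ----------------------------------------------------------------------
# Linear family
# ----------------------------------------------------------------------
class TestLinearFit:
    def test_exact_interaction_fit_no_noise(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=30)
        g = rng.binomial(2, 0.4, 30).astype(float)
        fit = fit_linear_gxe(g * e, e, g)
        np.testing.assert_allclose(fit.coefficients, [0, 0, 0, 1], atol=1e-10)
        assert fit.se("model") < 1e-10 and fit.se("robust") < 1e-10

    @pytest.mark.parametrize("flavor", ["hc0", "hc1", "hc2", "hc3"])
    def test_sandwich_matches_bruteforce_oracle(self, linear_fixture_20, flavor):
        y, e, g = linear_fixture_20
        fit = fit_linear_gxe(y, e, g, hc=flavor)
        X = np.column_stack([np.ones(20), e, g, g * e])
        beta, cov = _ols_sandwich_bruteforce(y, X, flavor)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        np.testing.assert_allclose(fit.cov_robust, cov, atol=1e-10)

    def test_matches_statsmodels_cross_check(self, linear_fixture_20):
        sm = pytest.importorskip("statsmodels.api")
        y, e, g = linear_fixture_20
        X = np.column_stack([np.ones(20), e, g, g * e])
        res = sm.OLS(y, X).fit()
        fit = fit_linear_gxe(y, e, g, hc="hc3")
        np.testing.assert_allclose(fit.cov_model, res.cov_params(), atol=1e-10)
        np.testing.assert_allclose(fit.cov_robust, res.get_robustcov_results(
            "HC3").cov_params(), atol=1e-10)

    def test_batch_equals_single_fits(self, small_linear_cohort):
        coh = small_linear_cohort
        b, vm, vr, ok = _linear_scan_batch(coh.phenotype, coh.exposure,
                                           coh.genotypes[:, :20])
        for j in range(20):
            f = fit_linear_gxe(coh.phenotype, coh.exposure,
                               coh.genotypes[:, j])
            assert np.isclose(b[j], f.beta_ge, atol=1e-10)
            assert np.isclose(np.sqrt(vr[j]), f.se("robust"), atol=1e-10)
            assert np.isclose(np.sqrt(vm[j]), f.se("model"), atol=1e-10)

    def test_se_flavors_estimate_same_quantity_under_correct_model(self):
        """Homoskedastic correct model: robust and model-based SEs estimate
        the same quantity.  The HC1 flavor agrees tightly in the median;
        HC3 sits a few percent higher by design (leverage correction)."""
        cfg = ScenarioConfig(n_subjects=1000, n_loci=2000, seed=17)
        coh = simulate_cohort(cfg)
        ok1 = genome_scan(coh, hc="hc1").converged()
        assert 0.98 < np.median(ok1.se_robust / ok1.se_model) < 1.02
        ok3 = genome_scan(coh, hc="hc3").converged()
        assert 0.98 < np.median(ok3.se_robust / ok3.se_model) < 1.06

    def test_shift_and_scale_equivariance(self, linear_fixture_20):
        y, e, g = linear_fixture_20
        base = fit_linear_gxe(y, e, g)
        shifted = fit_linear_gxe(y + 7.0, e, g)
        np.testing.assert_allclose(shifted.coefficients[0],
                                   base.coefficients[0] + 7.0, atol=1e-9)
        np.testing.assert_allclose(shifted.coefficients[1:],
                                   base.coefficients[1:], atol=1e-9)
        scaled = fit_linear_gxe(y, 2.0 * e, g)
        np.testing.assert_allclose(scaled.coefficients[1], base.coefficients[1] / 2,
                                   atol=1e-9)
        np.testing.assert_allclose(scaled.coefficients[3], base.coefficients[3] / 2,
                                   atol=1e-9)
        np.testing.assert_allclose(scaled.coefficients[2], base.coefficients[2],
                                   atol=1e-9)

    def test_monomorphic_locus_flagged_not_raised(self, linear_fixture_20):
        y, e, _ = linear_fixture_20
        fit = fit_linear_gxe(y, e, np.zeros(20))
        assert not fit.converged


# ----------------------------------------------------------------------
# Logistic family
# ----------------------------------------------------------------------
class TestLogisticFit:
    def test_score_stationarity(self, logistic_fixture_30):
        y, e, g = logistic_fixture_30
        fit = fit_logistic_gxe(y, e, g)
        assert fit.converged
        X = np.column_stack([np.ones(30), e, g, g * e])
        mu = 1 / (1 + np.exp(-(X @ fit.coefficients)))
        assert np.linalg.norm(X.T @ (y - mu)) < 1e-8

    def test_matches_generic_optimizer_oracle(self, logistic_fixture_30):
        y, e, g = logistic_fixture_30
        fit = fit_logistic_gxe(y, e, g)
        X = np.column_stack([np.ones(30), e, g, g * e])
        res = optimize.minimize(_logistic_nll, np.zeros(4), args=(y, X),
                                method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 500})
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-6)

    @pytest.mark.parametrize("flavor", ["hc0", "hc3"])
    def test_sandwich_matches_direct_summation(self, logistic_fixture_30,
                                               flavor):
        y, e, g = logistic_fixture_30
        fit = fit_logistic_gxe(y, e, g, hc=flavor)
        X = np.column_stack([np.ones(30), e, g, g * e])
        mu = 1 / (1 + np.exp(-(X @ fit.coefficients)))
        A = np.zeros((4, 4))
        for i in range(30):
            A += np.outer(X[i], X[i]) * mu[i] * (1 - mu[i])
        Ainv = np.linalg.inv(A)
        B = np.zeros((4, 4))
        for i in range(30):
            w = 1.0
            if flavor == "hc3":
                h = mu[i] * (1 - mu[i]) * float(X[i] @ Ainv @ X[i])
                w = 1.0 / (1.0 - h) ** 2
            B += np.outer(X[i], X[i]) * (y[i] - mu[i]) ** 2 * w
        np.testing.assert_allclose(fit.cov_model, Ainv, atol=1e-10)
        np.testing.assert_allclose(fit.cov_robust, Ainv @ B @ Ainv, atol=1e-10)

    def test_hc0_flavor_matches_statsmodels_glm(self, logistic_fixture_30):
        sm = pytest.importorskip("statsmodels.api")
        y, e, g = logistic_fixture_30
        X = np.column_stack([np.ones(30), e, g, g * e])
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        fit = fit_logistic_gxe(y, e, g, hc="hc0")
        np.testing.assert_allclose(fit.cov_robust, res.cov_params(), atol=1e-8)

    def test_separation_flagged(self):
        e = np.linspace(-2, 2, 20)
        g = (e > 0).astype(float)
        y = (e > 0).astype(float)
        fit = fit_logistic_gxe(y, e, g)
        assert not fit.converged

    def test_single_class_flagged(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=20)
        g = rng.binomial(2, 0.3, 20).astype(float)
        assert not fit_logistic_gxe(np.ones(20), e, g).converged


# ----------------------------------------------------------------------
# Cox family
# ----------------------------------------------------------------------
class TestCoxFit:
    def test_one_parameter_golden_section_oracle(self):
        """5 subjects, distinct event times, one binary covariate, all
        events: Newton solution equals a 1-D scalar-optimizer maximum of the
        independently coded partial likelihood."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        status = np.ones(5, dtype=int)
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0])[:, None]
        res = optimize.minimize_scalar(
            lambda b: -_cox_partial_loglik_bruteforce(b, t, status, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        fit = fit_cox_gxe(t, status, x[:, 0], g=None)
        assert fit.converged
        assert abs(fit.coefficients[0] - res.x) < 1e-6

    def test_matches_frozen_r_coxph_reference(self, cox_fixture_30):
        """Coefficients and both covariances equal survival::coxph
        (ties='breslow', robust=TRUE) on the same fixture."""
        t, status, x = cox_fixture_30
        fit = fit_cox_gxe(t, status, x[:, 0], g=None, covariates=x[:, 1])
        r_beta = np.array([0.001160015215, 0.763120167684])
        r_naive = np.array([[0.054289116132, -0.021202709495],
                            [-0.021202709495, 0.281416009849]])
        r_robust = np.array([[0.033664759398, -0.063918700446],
                             [-0.063918700446, 0.375300843326]])
        np.testing.assert_allclose(fit.coefficients, r_beta, atol=1e-7)
        np.testing.assert_allclose(fit.cov_model, r_naive, atol=1e-7)
        np.testing.assert_allclose(fit.cov_robust, r_robust, atol=1e-7)

    def test_sandwich_matches_direct_summation(self, cox_fixture_30):
        t, status, x = cox_fixture_30
        fit = fit_cox_gxe(t, status, x[:, 0], g=None, covariates=x[:, 1])
        Iinv, V = _cox_sandwich_bruteforce(fit.coefficients, t, status, x)
        np.testing.assert_allclose(fit.cov_model, Iinv, atol=1e-8)
        np.testing.assert_allclose(fit.cov_robust, V, atol=1e-8)

    def test_lifelines_cross_check(self, survival_cohort_small):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        coh = survival_cohort_small
        g = coh.genotypes[:, 0].astype(float)
        fit = fit_cox_gxe(coh.time, coh.status, coh.exposure, g)
        df = pd.DataFrame({"t": coh.time, "s": coh.status.astype(int),
                           "e": coh.exposure, "g": g, "ge": g * coh.exposure})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="s")
        np.testing.assert_allclose(fit.coefficients,
                                   cph.params_[["e", "g", "ge"]].values,
                                   atol=1e-5)
        np.testing.assert_allclose(
            fit.cov_model,
            cph.variance_matrix_.loc[["e", "g", "ge"], ["e", "g", "ge"]].values,
            atol=1e-5)

    def test_null_recovery_large_sample(self):
        rng = np.random.default_rng(3)
        n = 10_000
        t = rng.exponential(1.0, n)
        x = rng.binomial(1, 0.5, n).astype(float)
        fit = fit_cox_gxe(t, np.ones(n, dtype=int), x, g=None)
        assert abs(fit.coefficients[0]) < 3 * fit.se("robust", 0)

    def test_no_events_rejected(self):
        with pytest.raises(GxescanError):
            fit_cox_gxe(np.ones(5), np.zeros(5, dtype=int),
                        np.arange(5.0), np.zeros(5))


# ----------------------------------------------------------------------
# Tests on fits
# ----------------------------------------------------------------------
def _toy_fit(beta_ge, var_ge):
    cov = np.diag([1.0, 1.0, 1.0, var_ge])
    return GxEFit(np.array([0.0, 0.0, 0.0, beta_ge]), ["const", "e", "g", "g:e"],
                  cov, cov, True, 100, "linear", idx_g=2, idx_ge=3)


class TestWaldLrtJoint:
    def test_zero_beta_gives_p_one(self):
        res = wald_test(_toy_fit(0.0, 1.0))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile_oracle(self):
        fit = _toy_fit(np.sqrt(3.841459), 1.0)
        res = wald_test(fit, "model")
        assert abs(res.p_value - 0.05) < 1e-6
        assert abs(res.p_value - stats.chi2.sf(3.841459, 1)) < 1e-12

    def test_chi2_median_maps_to_half(self):
        res = wald_test(_toy_fit(np.sqrt(0.4549), 1.0))
        assert abs(res.p_value - 0.5) < 1e-3

    def test_zero_se_flagged(self):
        res = wald_test(_toy_fit(1.0, 0.0))
        assert np.isnan(res.p_value)

    def test_lrt_nested_fits_df_and_sign(self, linear_fixture_20):
        y, e, g = linear_fixture_20
        fit = fit_linear_gxe(y, e, g)
        null = fit_linear_gxe(y, e, g=None)
        res = lrt_test(fit, null)
        assert res.df == 2 and res.statistic >= 0
        with pytest.raises(GxescanError):
            lrt_test(null, fit)          # not nested in this order

    def test_lrt_zero_when_no_improvement(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=50)
        y = e.copy()          # no genotype contribution at all, no noise
        g = rng.binomial(2, 0.4, 50).astype(float)
        full = fit_linear_gxe(y, e, g)
        null = fit_linear_gxe(y, e, g=None)
        res = lrt_test(full, null)
        assert res.statistic < 1e-6 and res.p_value > 0.999

    def test_lrt_not_defined_for_cox(self, cox_fixture_30):
        t, status, x = cox_fixture_30
        f = fit_cox_gxe(t, status, x[:, 0], x[:, 1])
        with pytest.raises(NotSupportedError):
            lrt_test(f, f)

    def test_joint_wald_diagonal_block_sums_1df_stats(self):
        cov = np.diag([1.0, 1.0, 0.5, 2.0])
        fit = GxEFit(np.array([0.0, 0.0, 1.0, 2.0]),
                     ["const", "e", "g", "g:e"], cov, cov, True, 100,
                     "linear", idx_g=2, idx_ge=3)
        joint = joint_wald_test(fit, "model")
        w_g = fit.coefficients[2] ** 2 / cov[2, 2]
        w_ge = fit.coefficients[3] ** 2 / cov[3, 3]
        assert joint.df == 2
        assert abs(joint.statistic - (w_g + w_ge)) < 1e-12

    def test_misspecification_inflates_lrt_but_not_robust_joint(self):
        """Quadratic truth fitted as linear: LRT and model-based Wald scans
        inflate together, the robust joint test stays calibrated."""
        cfg = ScenarioConfig(n_subjects=500, n_loci=1000, mean_model="quadratic",
                             coefficients=dict_to_coef(0.0, 1.0, 1.0, 1.0),
                             seed=23)
        coh = simulate_cohort(cfg)
        lrt_stats, joint_stats = [], []
        for j in range(coh.n_loci):
            g = coh.genotypes[:, j]
            full = fit_linear_gxe(coh.phenotype, coh.exposure, g)
            null = fit_linear_gxe(coh.phenotype, coh.exposure, g=None)
            lrt_stats.append(lrt_test(full, null).statistic)
            joint_stats.append(joint_wald_test(full, "robust").statistic)
        lam_lrt = np.median(lrt_stats) / stats.chi2.ppf(0.5, 2)
        lam_joint = np.median(joint_stats) / stats.chi2.ppf(0.5, 2)
        scan = genome_scan(coh)
        from gxescan import genomic_lambda
        lam_model = genomic_lambda(scan.converged().chi2_model.to_numpy())
        assert lam_model > 1.3
        assert lam_lrt > 1.3
        assert 0.8 < lam_joint < 1.2


# ----------------------------------------------------------------------
# Genome scan
# ----------------------------------------------------------------------
class TestGenomeScan:
    def test_empty_scan(self):
        rng = np.random.default_rng(0)
        coh = Cohort(exposure=rng.normal(size=10),
                     genotypes=np.empty((10, 0)), maf=np.empty(0),
                     phenotype=rng.normal(size=10))
        scan = genome_scan(coh)
        assert scan.n_loci == 0

    def test_chi2_reconstructable_from_fields(self, small_linear_cohort):
        scan = genome_scan(small_linear_cohort).validate()
        ok = scan.converged()
        np.testing.assert_allclose((ok.beta_gxe / ok.se_robust) ** 2,
                                   ok.chi2_robust, atol=1e-10, rtol=1e-10)

    def test_low_mac_and_monomorphic_excluded(self):
        rng = np.random.default_rng(4)
        n = 200
        e = rng.normal(size=n)
        y = e + rng.normal(size=n)
        G = np.column_stack([
            np.zeros(n),                                    # monomorphic
            np.r_[np.ones(2), np.zeros(n - 2)],             # MAC 2
            rng.binomial(2, 0.3, n),
        ])
        coh = Cohort(exposure=e, genotypes=G, maf=np.array([0.0, 0.005, 0.3]),
                     phenotype=y)
        scan = genome_scan(coh)
        assert list(scan.table.status_code) == ["low_mac", "low_mac", "ok"]

    def test_missing_genotypes_complete_case(self):
        rng = np.random.default_rng(5)
        n = 300
        e = rng.normal(size=n)
        y = e + rng.normal(size=n)
        g = rng.binomial(2, 0.3, n).astype(float)
        gm = g.copy()
        gm[:10] = np.nan
        coh = Cohort(exposure=e, genotypes=gm[:, None], maf=np.array([0.3]),
                     phenotype=y)
        scan = genome_scan(coh)
        assert scan.table.n_used[0] == n - 10
        direct = fit_linear_gxe(y[10:], e[10:], g[10:])
        assert np.isclose(scan.table.beta_gxe[0], direct.beta_ge, atol=1e-10)

    def test_robust_variance_tracks_sampling_variance(self):
        """Mean sandwich variance estimate matches the empirical variance of
        beta_GE over independent replicates (correct and mis-specified);
        the model-based estimate only matches under the correct model."""
        from gxescan import run_decomposition
        correct = ScenarioConfig(n_subjects=300, n_loci=1, seed=41)
        quad = correct.replace(mean_model="quadratic",
                               coefficients=dict_to_coef(0.0, 1.0, 1.0, 1.0))
        res_c = run_decomposition(correct, n_outer=40, n_inner=50, seed=41)
        res_q = run_decomposition(quad, n_outer=40, n_inner=50, seed=42)
        assert 0.9 < res_c.mean_cov_robust / res_c.var_all_random < 1.1
        assert 0.9 < res_q.mean_cov_robust / res_q.var_all_random < 1.1
        assert 0.9 < res_c.mean_cov_model / res_c.var_all_random < 1.1
        assert res_q.mean_cov_model / res_q.var_all_random < 0.6


def dict_to_coef(i, l, q, s):
    from gxescan import Coefficients
    return Coefficients(intercept=i, linear=l, quadratic=q, noise_sd=s)
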