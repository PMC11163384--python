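"""REML likelihood, AI-REML fitting, derived parameters and the covariance LRT."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from lgcblup import (GRM, SimConfig, VarianceComponents, center_genotypes,
                     derive_params, fit_reml, lrt_zero_covariance,
                     make_grm, make_model_spec, reml_loglik, simulate_dataset)


def _single_pop_spec(g, pheno, pop, grm):
    ids = g.individual_ids[g.population == pop]
    keep = g.indices_of(ids)
    sub = GRM(values=grm.values[np.ix_(keep, keep)], individual_ids=ids)
    return make_model_spec(sub, g, pheno, train_ids=ids, n_traits=1)


class TestLoglik:
    def test_matches_dense_projection_formula(self, small_dataset, small_grm):
        """Direct evaluation of -1/2[log|V| + log|X'V^-1 X| + y'Py + c] on a
        6-record instance, with V assembled longhand."""
        g, pheno, _, _ = small_dataset
        ids = np.concatenate([g.individual_ids[:3], g.individual_ids[-3:]])
        spec = make_model_spec(small_grm, g, pheno, train_ids=ids, n_traits=2)
        vc = VarianceComponents(M=np.array([[[0.7, 0.2], [0.2, 0.5]]]),
                                resid=np.array([1.1, 0.9]))
        idx = g.indices_of(ids)
        t = (np.arange(6) >= 3).astype(int)
        V = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                V[i, j] = vc.M[0][t[i], t[j]] * small_grm.values[idx[i], idx[j]]
        V += np.diag(vc.resid[t])
        X = np.zeros((6, 2))
        X[np.arange(6), t] = 1.0
        y = pheno.values_for(ids)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        expected = -0.5 * (np.linalg.slogdet(V)[1]
                           + np.linalg.slogdet(XtViX)[1]
                           + y @ P @ y + 4 * np.log(2 * np.pi))
        assert reml_loglik(spec, vc) == pytest.approx(expected, abs=1e-9)

    def test_decoupled_bivariate_equals_sum_of_single_population_fits(
            self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        spec = make_model_spec(small_grm, g, pheno, n_traits=2)
        joint = fit_reml(spec, fix_cov_zero=(0,), tol=1e-10)
        singles = sum(
            fit_reml(_single_pop_spec(g, pheno, pop, small_grm), tol=1e-10).loglik
            for pop in g.populations)
        assert joint.loglik == pytest.approx(singles, abs=1e-6)


class TestFitREML:
    def test_matches_grid_search_oracle_single_trait(self):
        """n=20 single-trait fit agrees with a dense grid over (sa2, se2)."""
        cfg = SimConfig(seed=9, n_per_pop=20, n_pop2=5, blocks_per_chrom=2,
                        snps_per_block=30, h2=(0.5, 0.5)).resolved()
        g, pheno, _ = simulate_dataset(cfg)
        grm = make_grm(center_genotypes(g), individual_ids=g.individual_ids)
        spec = _single_pop_spec(g, pheno, "POP1", grm)
        vc = fit_reml(spec, tol=1e-10)
        grid = np.linspace(0.02, 5.0, 90)
        lls = [(reml_loglik(spec, VarianceComponents(
            M=np.array([[[sa]]]), resid=np.array([se]))), sa, se)
            for sa in grid for se in grid]
        _, sa, se = max(lls)
        step = grid[1] - grid[0]
        assert vc.M[0, 0, 0] == pytest.approx(sa, abs=step)
        assert vc.resid[0] == pytest.approx(se, abs=step)

    def test_scaling_response_rescales_components_not_ratios(
            self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        import lgcblup
        scaled = lgcblup.PhenotypeTable(
            pheno.frame.assign(trait=pheno.frame["trait"] * 3.0))
        a = fit_reml(make_model_spec(small_grm, g, pheno, n_traits=2), tol=1e-9)
        b = fit_reml(make_model_spec(small_grm, g, scaled, n_traits=2), tol=1e-9)
        np.testing.assert_allclose(b.M, 9.0 * a.M, rtol=1e-3)
        np.testing.assert_allclose(derive_params(b).h2, derive_params(a).h2,
                                   atol=1e-4)
        np.testing.assert_allclose(derive_params(b).r_g, derive_params(a).r_g,
                                   atol=1e-4)

    def test_invariant_to_individual_reordering(self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        spec = make_model_spec(small_grm, g, pheno, n_traits=2)
        perm = np.random.default_rng(1).permutation(g.individual_ids)
        spec_p = make_model_spec(small_grm, g, pheno, train_ids=perm, n_traits=2)
        a, b = fit_reml(spec, tol=1e-9), fit_reml(spec_p, tol=1e-9)
        np.testing.assert_allclose(a.M, b.M, atol=1e-5)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)

    def test_pure_noise_recovers_zero_heritability(self):
        h2s = []
        for seed in range(20):
            cfg = SimConfig(seed=100 + seed, n_per_pop=120, n_pop2=5,
                            blocks_per_chrom=2, snps_per_block=30,
                            h2=(0.5, 0.5)).resolved()
            g, pheno, _ = simulate_dataset(cfg)
            # destroy the genetic signal: response is fresh iid noise
            rng = np.random.default_rng(seed)
            import lgcblup
            pheno = lgcblup.PhenotypeTable(pheno.frame.assign(
                trait=rng.standard_normal(len(pheno.frame))))
            grm = make_grm(center_genotypes(g), individual_ids=g.individual_ids)
            spec = _single_pop_spec(g, pheno, "POP1", grm)
            h2s.append(derive_params(fit_reml(spec, tol=1e-6)).h2[0])
        assert np.mean(h2s) < 0.05

    def test_monotone_loglik_against_default_init(self, small_dataset,
                                                  small_grm):
        g, pheno, _, _ = small_dataset
        spec = make_model_spec(small_grm, g, pheno, n_traits=2)
        init = VarianceComponents(M=np.array([[[2.0, 0.0], [0.0, 2.0]]]),
                                  resid=np.array([2.0, 2.0]))
        ll_init = reml_loglik(spec, init)
        vc = fit_reml(spec, init=init, tol=1e-8)
        assert vc.loglik >= ll_init - 1e-9


class TestDerivedParams:
    @pytest.mark.parametrize("M, resid, h2, rg", [
        (np.array([[[1.0, 0.0], [0.0, 1.0]]]), np.array([1.0, 1.0]),
         [0.5, 0.5], [0.0]),
        (np.array([[[4.0, -1.0], [-1.0, 1.0]]]), np.array([1.0, 3.0]),
         [0.8, 0.25], [-0.5]),
    ])
    def test_formula_arithmetic(self, M, resid, h2, rg):
        dp = derive_params(VarianceComponents(M=M, resid=resid))
        np.testing.assert_allclose(dp.h2, h2)
        np.testing.assert_allclose(dp.r_g, rg)

    def test_zero_variance_kernel_flags_undefined_correlation(self):
        vc = VarianceComponents(M=np.array([[[0.0, 0.0], [0.0, 1.0]]]),
                                resid=np.array([1.0, 1.0]))
        assert np.isnan(derive_params(vc).r_g[0])

    def test_standard_errors_shrink_with_sample_size(self):
        ses = []
        for n in (40, 120):
            cfg = SimConfig(seed=3, n_per_pop=n, n_pop2=n,
                            block_r=np.full(10, 0.6)).resolved()
            g, pheno, _ = simulate_dataset(cfg)
            grm = make_grm(center_genotypes(g), individual_ids=g.individual_ids)
            vc = fit_reml(make_model_spec(grm, g, pheno, n_traits=2), tol=1e-7)
            ses.append(derive_params(vc).h2_se[0])
        assert 0 < ses[1] < ses[0]


class TestCovarianceLRT:
    def test_chi_square_reference_distribution(self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        spec = make_model_spec(small_grm, g, pheno, n_traits=2)
        stat, p = lrt_zero_covariance(spec, 0, tol=1e-8)
        assert stat >= 0.0
        assert p == pytest.approx(stats.chi2.sf(stat, 1))
        # the quantile anchor: a statistic of 3.841 sits at p ~= 0.05
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_strong_shared_signal_rejects(self):
        cfg = SimConfig(seed=21, n_per_pop=150, n_pop2=100,
                        block_r=np.full(10, 0.9)).resolved()
        g, pheno, _ = simulate_dataset(cfg)
        grm = make_grm(center_genotypes(g), individual_ids=g.individual_ids)
        spec = make_model_spec(grm, g, pheno, n_traits=2)
        stat, p = lrt_zero_covariance(spec, 0, tol=1e-7)
        assert p < 0.01
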