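"""BLUP solvers and the five prediction estimators."""

import numpy as np
import pytest
from sklearn.base import clone

from lgcblup import (GRM, LGCModel1, LGCModel2, MTGBLUP, ModelSpec,
                     PhenotypeTable, STGBLUP, STGBLUPCombined,
                     VarianceComponents, classify_model1, classify_model2,
                     estimate_lgc, gblup_solve, gblup_solve_mme,
                     run_mtgblup, run_stgblup)
from lgcblup.lgc import LGCRecord


class TestGblupSolve:
    def test_two_individual_closed_form(self):
        """One observed record y=1, G=[[1,.5],[.5,1]], sa2=se2=1, no fixed
        effects: a1 = 0.5, a2 = 0.25 by the conditional expectation."""
        G = GRM(values=np.array([[1.0, 0.5], [0.5, 1.0]]),
                individual_ids=np.array(["a", "b"]))
        spec = ModelSpec(kernels=[G], y=np.array([1.0]),
                         record_indiv=np.array([0]),
                         record_trait=np.array([0]), n_traits=1,
                         X=np.zeros((1, 0)))
        vc = VarianceComponents(M=np.array([[[1.0]]]), resid=np.array([1.0]))
        _, total = gblup_solve(spec, vc, np.array([0, 1]), np.array([0, 0]))
        np.testing.assert_allclose(total, [0.5, 0.25])

    def test_zero_genetic_variance_shrinks_to_zero(self):
        G = GRM(values=np.eye(3), individual_ids=np.arange(3))
        spec = ModelSpec(kernels=[G], y=np.array([1.0, -2.0]),
                         record_indiv=np.array([0, 1]),
                         record_trait=np.array([0, 0]), n_traits=1,
                         X=np.ones((2, 1)))
        vc = VarianceComponents(M=np.array([[[1e-12]]]), resid=np.array([1.0]))
        _, total = gblup_solve(spec, vc, np.arange(3), np.zeros(3, int))
        np.testing.assert_allclose(total, 0.0, atol=1e-10)

    def test_mme_and_gls_paths_agree(self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        from lgcblup import make_model_spec
        # jitter the GRM so M (x) G is invertible for the MME route
        Gpd = GRM(values=small_grm.values + 1e-6 * np.eye(small_grm.n),
                  individual_ids=small_grm.individual_ids)
        rng = np.random.default_rng(8)
        train = rng.choice(g.individual_ids, size=100, replace=False)
        spec = make_model_spec(Gpd, g, pheno, train_ids=train, n_traits=2)
        vc = VarianceComponents(M=np.array([[[0.8, 0.3], [0.3, 0.6]]]),
                                resid=np.array([1.0, 1.2]))
        pred = g.indices_of(np.setdiff1d(g.individual_ids, train)[:20])
        trait = g.population_index[pred]
        c1, t1 = gblup_solve(spec, vc, pred, trait)
        c2, t2 = gblup_solve_mme(spec, vc, pred, trait)
        np.testing.assert_allclose(t1, t2, atol=1e-8)
        np.testing.assert_allclose(c1, c2, atol=1e-8)


class TestSTGBLUP:
    def test_sklearn_protocol(self):
        est = STGBLUP(population="POP1", tol=1e-6)
        params = est.get_params()
        assert params["population"] == "POP1"
        assert clone(est).get_params() == params

    def test_empty_training_set_is_error(self, small_dataset):
        g, pheno, _, _ = small_dataset
        with pytest.raises(ValueError):
            STGBLUP(population="POP1").fit(
                g, pheno, train_ids=g.individual_ids[g.population == "POP2"])

    def test_predicts_only_own_population(self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        train = g.individual_ids[:-30]
        est = STGBLUP(population="POP2", grm=small_grm, tol=1e-6)
        result = est.fit(g, pheno, train).predict(return_components=True)
        assert set(result.table["pop"]) == {"POP2"}


class TestSTGBLUPCombined:
    def test_refuses_non_commensurable_responses(self, small_dataset):
        g, pheno, _, _ = small_dataset
        flagged = PhenotypeTable(pheno.frame.copy(), commensurable=False)
        with pytest.raises(ValueError, match="not applicable"):
            STGBLUPCombined().fit(g, flagged)

    def test_reports_single_genetic_variance(self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        est = STGBLUPCombined(grm=small_grm, tol=1e-6).fit(g, pheno)
        assert est.vc_.M.shape == (1, 1, 1)
        assert est.spec_.X.shape[1] == 2   # per-population intercepts


class TestMTGBLUP:
    def test_requires_two_populations(self, small_dataset):
        g, pheno, _, _ = small_dataset
        keep = np.flatnonzero(g.population == "POP1")
        import lgcblup
        g1 = lgcblup.GenotypeMatrix(
            codes=g.codes[keep], snp_ids=g.snp_ids, chrom=g.chrom,
            pos_bp=g.pos_bp, individual_ids=g.individual_ids[keep],
            population=g.population[keep])
        with pytest.raises(ValueError, match="two populations"):
            MTGBLUP().fit(g1, pheno, train_ids=g1.individual_ids)

    def test_zero_covariance_fit_matches_stgblup_gebvs(self, small_dataset,
                                                       small_grm):
        """With the between-population covariance forced to zero the
        bivariate predictions decouple into the two single-trait runs."""
        from lgcblup import fit_reml, make_model_spec
        g, pheno, _, _ = small_dataset
        rng = np.random.default_rng(9)
        train = rng.choice(g.individual_ids, size=110, replace=False)
        val = np.setdiff1d(g.individual_ids, train)
        spec = make_model_spec(small_grm, g, pheno, train_ids=train, n_traits=2)
        vc0 = fit_reml(spec, fix_cov_zero=(0,), tol=1e-10)
        vi = g.indices_of(val)
        _, mt = gblup_solve(spec, vc0, vi, g.population_index[vi])
        st = np.full(val.size, np.nan)
        for pop in g.populations:
            est = STGBLUP(population=pop, grm=small_grm, tol=1e-10,
                          max_iter=400).fit(g, pheno, train)
            sel = g.population[vi] == pop
            st[sel] = est.predict(val[sel])
        np.testing.assert_allclose(mt, st, atol=1e-4)

    def test_wrapper_delegates_to_estimator(self, small_dataset, small_grm):
        g, pheno, _, _ = small_dataset
        train = g.individual_ids[:-40]
        val = g.individual_ids[-40:]
        res = run_mtgblup(g, pheno, train_ids=train, predict_ids=val,
                          grm=small_grm, tol=1e-6)
        est = MTGBLUP(grm=small_grm, tol=1e-6).fit(g, pheno, train)
        np.testing.assert_allclose(res.gebv, est.predict(val), atol=1e-10)


@pytest.fixture(scope="module")
def fitted_pieces(small_dataset, small_grm, true_partition):
    g, pheno, _, _ = small_dataset
    rng = np.random.default_rng(10)
    train = rng.choice(g.individual_ids, size=110, replace=False)
    val = np.setdiff1d(g.individual_ids, train)
    recs = estimate_lgc(g, pheno, true_partition, train_ids=train)
    return g, pheno, train, val, recs


class TestLGCModels:
    def test_totals_are_exact_component_sums(self, fitted_pieces, small_grm,
                                             true_partition):
        g, pheno, train, val, recs = fitted_pieces
        est = LGCModel2(grm=small_grm, partition=true_partition,
                        lgc_records=recs, tol=1e-6).fit(g, pheno, train)
        res = est.predict(val, return_components=True)
        comp_cols = [c for c in res.table.columns if c.startswith("gebv_")]
        np.testing.assert_array_equal(
            res.table[comp_cols].sum(axis=1).to_numpy(), res.gebv)

    def test_sig_equal_to_all_snps_collapses_to_mtgblup(
            self, fitted_pieces, small_grm, true_partition):
        g, pheno, train, val, recs = fitted_pieces
        # degenerate classification: every block is SIG, NON is empty
        assignment = {b: "SIG" for b in range(6)}
        from lgcblup import RegionClasses
        classes = RegionClasses("MODEL1", assignment,
                                true_partition.class_snp_sets(assignment))
        m1 = LGCModel1(grm=small_grm, partition=true_partition,
                       classes=classes, tol=1e-8).fit(g, pheno, train)
        mt = MTGBLUP(grm=small_grm, tol=1e-8).fit(g, pheno, train)
        np.testing.assert_allclose(m1.predict(val), mt.predict(val), atol=1e-4)

    def test_all_res_collapses_to_mtgblup(self, fitted_pieces, small_grm,
                                          true_partition):
        g, pheno, train, val, _ = fitted_pieces
        zero = [LGCRecord(b, 0.0, 0.9, .1, .1, 25) for b in range(6)]
        m2 = LGCModel2(grm=small_grm, partition=true_partition,
                       lgc_records=zero, tol=1e-8).fit(g, pheno, train)
        assert set(m2.classes_.assignment.values()) == {"RES"}
        mt = MTGBLUP(grm=small_grm, tol=1e-8).fit(g, pheno, train)
        np.testing.assert_allclose(m2.predict(val), mt.predict(val), atol=1e-4)

    def test_pos_neg_covariance_signs_recovered(self, fitted_pieces,
                                                small_grm, true_partition):
        """On planted ±0.9 blocks the fitted POS kernel covariance is
        positive and the NEG kernel covariance negative."""
        g, pheno, train, val, _ = fitted_pieces
        truth_classes = classify_model2(
            [LGCRecord(b, r, 0.01, .1, .1, 25) for b, r in
             enumerate([0.9, 0.0, -0.9, 0.0, 0.9, 0.0])],
            true_partition, threshold=0.5)
        est = LGCModel2(grm=small_grm, partition=true_partition,
                        classes=truth_classes, tol=1e-6).fit(g, pheno, train)
        labels = est.spec_.kernel_labels
        M = est.vc_.M
        assert M[labels.index("POS"), 0, 1] > 0
        assert M[labels.index("NEG"), 0, 1] < 0
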