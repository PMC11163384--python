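"""GBLUP prediction models as scikit-learn style estimators.

Five models, all solved by the same generalized-least-squares / conditional-
expectation BLUP core (:func:`gblup_solve`):

* :class:`STGBLUP` — single-trait GBLUP within one population;
* :class:`STGBLUPCombined` — single-trait GBLUP on the pooled populations
  (one genetic variance, per-population intercepts);
* :class:`MTGBLUP` — bivariate GBLUP treating the trait in the two
  populations as two correlated traits with one genome-wide kernel;
* :class:`LGCModel1` — bivariate two-kernel GBLUP with SIG/NON region
  kernels chosen by local-genetic-correlation significance;
* :class:`LGCModel2` — bivariate three-kernel GBLUP with POS/NEG/RES region
  kernels chosen by local-genetic-correlation sign and magnitude.

Each estimator follows the sklearn protocol: hyper-parameters in
``__init__`` (untouched), ``fit(genotypes, phenotypes, train_ids=...)``
estimating variance components by REML on the training records only,
fitted state in trailing-underscore attributes, and ``predict`` returning
per-kernel and total GEBVs.  Validation individuals contribute genotypes to
the kernels but never phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_io import GenotypeMatrix, PhenotypeTable
from .grm import GRM, center_genotypes, combine_grms, grm_for_partition, make_grm
from .lgc import RegionClasses, classify_model1, classify_model2, estimate_lgc
from .ld_partition import partition_genome
from .reml import (ModelSpec, VarianceComponents, derive_params, fit_reml,
                   make_model_spec)

__all__ = [
    "PredictionResult",
    "gblup_solve",
    "gblup_solve_mme",
    "STGBLUP",
    "STGBLUPCombined",
    "MTGBLUP",
    "LGCModel1",
    "LGCModel2",
    "run_stgblup",
    "run_stgblup_combined",
    "run_mtgblup",
    "run_lgc_model1",
    "run_lgc_model2",
]


@dataclass
class PredictionResult:
    """Per-individual GEBVs, per kernel and total.

    ``table`` has one row per requested individual with columns ``iid``,
    ``pop``, one ``gebv_<kernel>`` column per kernel and ``gebv`` (their
    exact sum).
    """

    table: pd.DataFrame
    model: str
    vc: VarianceComponents

    @property
    def gebv(self) -> np.ndarray:
        return self.table["gebv"].to_numpy()


def gblup_solve(
    spec: ModelSpec,
    vc: VarianceComponents,
    predict_indiv: np.ndarray,
    predict_trait: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP by the conditional-expectation route.

    Fixed effects by GLS; then for kernel k the GEBV of candidate i on trait
    t is ``â_{k,i} = Σ_j M_k[t, t_j] G_k[i, j] α_j`` with
    ``α = V⁻¹(y - X b̂)`` over the observed records.  Returns
    ``(components, total)`` where components has shape (n_candidates,
    n_kernels); the total is their exact sum.
    """
    from scipy import linalg

    from .reml import _build_V  # shared covariance assembly

    predict_indiv = np.asarray(predict_indiv, int)
    predict_trait = np.asarray(predict_trait, int)
    n_ind = spec.kernels[0].n
    if predict_indiv.size and predict_indiv.max() >= n_ind:
        raise ValueError("prediction individual missing from the kernels")
    V = _build_V(spec, vc.M, vc.resid)
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    ViX = linalg.cho_solve((c, low), spec.X, check_finite=False)
    Viy = linalg.cho_solve((c, low), spec.y, check_finite=False)
    beta = np.linalg.solve(spec.X.T @ ViX, spec.X.T @ Viy)
    alpha = Viy - ViX @ beta

    comps = np.empty((predict_indiv.size, spec.n_kernels))
    tj = spec.record_trait
    for k, grm in enumerate(spec.kernels):
        Gcross = grm.values[np.ix_(predict_indiv, spec.record_indiv)]
        Mw = vc.M[k][predict_trait[:, None], tj[None, :]]
        comps[:, k] = (Gcross * Mw) @ alpha
    return comps, comps.sum(axis=1)


def gblup_solve_mme(
    spec: ModelSpec,
    vc: VarianceComponents,
    predict_indiv: np.ndarray,
    predict_trait: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP by Henderson's mixed-model equations (dense, cross-check path).

    Builds the full MME with one stacked effect vector per kernel and solves
    directly.  Requires every ``M_k ⊗ G_k`` to be invertible, so it is a
    verification tool for small full-rank instances, not the production
    route; it must agree with :func:`gblup_solve` within numerical tolerance.
    """
    predict_indiv = np.asarray(predict_indiv, int)
    predict_trait = np.asarray(predict_trait, int)
    n_ind = spec.kernels[0].n
    nt = spec.n_traits
    nrec = spec.n_records
    slot = spec.record_trait * n_ind + spec.record_indiv  # trait-major stacking

    Z = np.zeros((nrec, nt * n_ind))
    Z[np.arange(nrec), slot] = 1.0
    Rinv = np.diag(1.0 / vc.resid[spec.record_trait])
    X = spec.X

    K = spec.n_kernels
    blocks = []
    for k in range(K):
        cov = np.kron(vc.M[k], spec.kernels[k].values)
        blocks.append(np.linalg.inv(cov))
    nu = nt * n_ind
    dim = X.shape[1] + K * nu
    A = np.zeros((dim, dim))
    b = np.zeros(dim)
    A[:X.shape[1], :X.shape[1]] = X.T @ Rinv @ X
    b[:X.shape[1]] = X.T @ Rinv @ spec.y
    ZtRZ = Z.T @ Rinv @ Z
    ZtRy = Z.T @ Rinv @ spec.y
    XtRZ = X.T @ Rinv @ Z
    for k in range(K):
        r0 = X.shape[1] + k * nu
        A[:X.shape[1], r0:r0 + nu] = XtRZ
        A[r0:r0 + nu, :X.shape[1]] = XtRZ.T
        b[r0:r0 + nu] = ZtRy
        for k2 in range(K):
            c0 = X.shape[1] + k2 * nu
            A[r0:r0 + nu, c0:c0 + nu] = ZtRZ
        A[r0:r0 + nu, r0:r0 + nu] += blocks[k]
    sol = np.linalg.solve(A, b)
    comps = np.empty((predict_indiv.size, K))
    for k in range(K):
        u = sol[X.shape[1] + k * nu: X.shape[1] + (k + 1) * nu]
        comps[:, k] = u[predict_trait * n_ind + predict_indiv]
    return comps, comps.sum(axis=1)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class _GBLUPBase(BaseEstimator):
    """Shared fit/predict machinery for all GBLUP variants."""

    _n_traits: int = 2
    _pooled: bool = False

    def __init__(self, trait=None, grm=None, tol=1e-8, max_iter=200):
        self.trait = trait
        self.grm = grm
        self.tol = tol
        self.max_iter = max_iter

    # subclasses build their kernel list from the training data
    def _kernels(self, g, pheno, train_ids) -> list[GRM]:
        raise NotImplementedError

    def _full_grm(self, g: GenotypeMatrix) -> GRM:
        if self.grm is not None:
            return self.grm
        return make_grm(center_genotypes(g), individual_ids=g.individual_ids)

    def _train_ids(self, g, pheno, train_ids):
        if train_ids is None:
            have = pheno.frame.loc[
                ~pheno.frame[self.trait or pheno.traits[0]].isna(), "iid"]
            train_ids = have.to_numpy()
        return np.asarray(train_ids)

    def fit(self, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
            train_ids=None):
        """Estimate variance components on the training records by REML."""
        train_ids = self._train_ids(genotypes, phenotypes, train_ids)
        if train_ids.size == 0:
            raise ValueError("empty training set")
        kernels = self._kernels(genotypes, phenotypes, train_ids)
        spec = make_model_spec(
            kernels, genotypes, phenotypes, trait=self.trait,
            train_ids=train_ids, n_traits=None if self._pooled else self._n_traits,
            pooled=self._pooled)
        self.vc_ = fit_reml(spec, tol=self.tol, max_iter=self.max_iter)
        self.derived_ = derive_params(self.vc_)
        self.spec_ = spec
        self.genotypes_ = genotypes
        self.train_ids_ = train_ids
        return self

    def _predictable_ids(self) -> np.ndarray:
        g = self.genotypes_
        mask = ~np.isin(g.individual_ids, self.train_ids_)
        ids = g.individual_ids[mask]
        return self._restrict_candidates(ids)

    def _restrict_candidates(self, ids: np.ndarray) -> np.ndarray:
        return ids

    def predict(self, ids=None, return_components: bool = False):
        """GEBVs for the requested individuals (default: all non-training).

        Returns the total GEBV array, or a :class:`PredictionResult` with
        per-kernel components when ``return_components`` is true.
        """
        if not hasattr(self, "vc_"):
            raise RuntimeError("estimator is not fitted")
        g = self.genotypes_
        ids = np.asarray(ids) if ids is not None else self._predictable_ids()
        kernel_ids = list(self.spec_.kernels[0].individual_ids)
        lookup = {iid: i for i, iid in enumerate(kernel_ids)}
        try:
            indiv = np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"individual {exc.args[0]!r} missing from the "
                             "fitted kernels") from exc
        g_rows = g.indices_of(ids)
        trait = g.population_index[g_rows] if self.spec_.n_traits == 2 \
            else np.zeros(indiv.size, int)
        comps, total = gblup_solve(self.spec_, self.vc_, indiv, trait)
        result = PredictionResult(
            table=pd.DataFrame({
                "iid": ids, "pop": g.population[g_rows],
                **{f"gebv_{lbl}": comps[:, k]
                   for k, lbl in enumerate(self.spec_.kernel_labels)},
                "gebv": total,
            }),
            model=type(self).__name__, vc=self.vc_)
        return result if return_components else total


class STGBLUP(_GBLUPBase):
    """Single-trait GBLUP within one population.

    Between-population information is ignored entirely: the kernel is the
    pooled-frequency GRM restricted to the chosen population's individuals.
    """

    _n_traits = 1

    def __init__(self, population=None, trait=None, grm=None, tol=1e-8,
                 max_iter=200):
        super().__init__(trait=trait, grm=grm, tol=tol, max_iter=max_iter)
        self.population = population

    def _pop_ids(self, g: GenotypeMatrix) -> np.ndarray:
        pop = self.population if self.population is not None else g.populations[0]
        ids = g.individual_ids[g.population == pop]
        if ids.size == 0:
            raise ValueError(f"no individuals in population {pop!r}")
        return ids

    def _train_ids(self, g, pheno, train_ids):
        ids = super()._train_ids(g, pheno, train_ids)
        keep = np.isin(ids, self._pop_ids(g))
        if not keep.any():
            raise ValueError("empty training set for this population")
        return ids[keep]

    def _restrict_candidates(self, ids):
        return ids[np.isin(ids, self._pop_ids(self.genotypes_))]

    def _kernels(self, g, pheno, train_ids):
        full = self._full_grm(g)
        keep = g.indices_of(self._pop_ids(g))
        sub = GRM(values=full.values[np.ix_(keep, keep)],
                  individual_ids=full.individual_ids[keep],
                  snp_set=full.snp_set, denom=full.denom, n_snps=full.n_snps)
        return [sub]

class STGBLUPCombined(_GBLUPBase):
    """Single-trait GBLUP over the pooled two-population reference.

    Assumes the responses of the two populations are commensurable (same
    trait definition and scale); refuses to fit otherwise.  A single genetic
    variance is estimated; per-population intercepts are always included.
    """

    _n_traits = 1
    _pooled = True

    def _kernels(self, g, pheno, train_ids):
        return [self._full_grm(g)]


class MTGBLUP(_GBLUPBase):
    """Bivariate GBLUP: the trait in the two populations as two correlated
    traits sharing one genome-wide genomic relationship kernel."""

    def _kernels(self, g, pheno, train_ids):
        if len(g.populations) < 2:
            raise ValueError("multi-trait model requires two populations")
        return [self._full_grm(g)]


class _LGCBase(_GBLUPBase):
    """Shared machinery for the partitioned-kernel (LGC) models."""

    def __init__(self, trait=None, grm=None, tol=1e-8, max_iter=200,
                 partition=None, block_grms=None, lgc_records=None,
                 classes=None, max_block_snps=200, min_snps=25, window=50,
                 lgc_tol=1e-4, lgc_max_iter=60):
        super().__init__(trait=trait, grm=grm, tol=tol, max_iter=max_iter)
        self.partition = partition
        self.block_grms = block_grms
        self.lgc_records = lgc_records
        self.classes = classes
        self.max_block_snps = max_block_snps
        self.min_snps = min_snps
        self.window = window
        self.lgc_tol = lgc_tol
        self.lgc_max_iter = lgc_max_iter

    def _classify(self, records, partition) -> RegionClasses:
        raise NotImplementedError

    def _kernels(self, g, pheno, train_ids):
        if len(g.populations) < 2:
            raise ValueError("partitioned-kernel models require two populations")
        partition = self.partition
        if partition is None and (self.classes is None or
                                  self.block_grms is not None):
            partition = partition_genome(center_genotypes(g),
                                         max_block_snps=self.max_block_snps,
                                         min_snps=self.min_snps,
                                         window=self.window)
        if self.classes is not None:
            classes = self.classes
            records = self.lgc_records
        else:
            records = self.lgc_records
            if records is None:
                records = estimate_lgc(g, pheno, partition, trait=self.trait,
                                       train_ids=train_ids, tol=self.lgc_tol,
                                       max_iter=self.lgc_max_iter)
            classes = self._classify(records, partition)
        self.partition_ = partition
        self.lgc_records_ = records
        self.classes_ = classes

        if self.block_grms is not None:
            # exact reconstruction: class GRM = denom-weighted block GRMs
            members: dict[str, list[GRM]] = {}
            for b in partition.blocks:
                label = classes.assignment[b.block_id]
                members.setdefault(label, []).append(
                    self.block_grms[b.block_id])
            grms = {lbl: combine_grms(gs, snp_set=lbl)
                    for lbl, gs in members.items()}
        else:
            grms = grm_for_partition(g, classes.snp_sets)
        order = [lbl for lbl in self._class_order if lbl in grms]
        if not order:
            raise ValueError("every region class is empty")
        return [grms[lbl] for lbl in order]


class LGCModel1(_LGCBase):
    """Two-kernel bivariate GBLUP on SIG / NON region classes.

    SIG regions are the ``top_k`` LD blocks with the smallest local
    genetic-correlation p-values (estimated on the training records); the
    remaining genome forms the NON kernel.  Total GEBV = SIG + NON
    components.
    """

    _class_order = ("SIG", "NON")

    def __init__(self, top_k=20, trait=None, grm=None, tol=1e-8, max_iter=200,
                 partition=None, block_grms=None, lgc_records=None,
                 classes=None, max_block_snps=200, min_snps=25, window=50,
                 lgc_tol=1e-4, lgc_max_iter=60):
        super().__init__(trait=trait, grm=grm, tol=tol, max_iter=max_iter,
                         partition=partition, block_grms=block_grms,
                         lgc_records=lgc_records, classes=classes,
                         max_block_snps=max_block_snps, min_snps=min_snps,
                         window=window, lgc_tol=lgc_tol,
                         lgc_max_iter=lgc_max_iter)
        self.top_k = top_k

    def _classify(self, records, partition):
        return classify_model1(records, partition, top_k=self.top_k)


class LGCModel2(_LGCBase):
    """Three-kernel bivariate GBLUP on POS / NEG / RES region classes.

    POS (NEG) regions have estimated local genetic correlation >= threshold
    (<= -threshold); everything else is RES.  Empty classes drop their
    kernel with a warning.  Total GEBV = POS + NEG + RES components.
    """

    _class_order = ("POS", "NEG", "RES")

    def __init__(self, threshold=0.5, trait=None, grm=None, tol=1e-8,
                 max_iter=200, partition=None, block_grms=None,
                 lgc_records=None, classes=None, max_block_snps=200,
                 min_snps=25, window=50, lgc_tol=1e-4, lgc_max_iter=60):
        super().__init__(trait=trait, grm=grm, tol=tol, max_iter=max_iter,
                         partition=partition, block_grms=block_grms,
                         lgc_records=lgc_records, classes=classes,
                         max_block_snps=max_block_snps, min_snps=min_snps,
                         window=window, lgc_tol=lgc_tol,
                         lgc_max_iter=lgc_max_iter)
        self.threshold = threshold

    def _classify(self, records, partition):
        return classify_model2(records, partition, threshold=self.threshold)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def run_stgblup(g, pheno, population, train_ids=None, predict_ids=None,
                **kwargs) -> PredictionResult:
    """Single-population GBLUP; see :class:`STGBLUP`."""
    est = STGBLUP(population=population, **kwargs).fit(g, pheno, train_ids)
    return est.predict(predict_ids, return_components=True)


def run_stgblup_combined(g, pheno, train_ids=None, predict_ids=None,
                         **kwargs) -> PredictionResult:
    """Pooled-reference single-trait GBLUP; see :class:`STGBLUPCombined`."""
    est = STGBLUPCombined(**kwargs).fit(g, pheno, train_ids)
    return est.predict(predict_ids, return_components=True)


def run_mtgblup(g, pheno, train_ids=None, predict_ids=None,
                **kwargs) -> PredictionResult:
    """Bivariate GBLUP; see :class:`MTGBLUP`."""
    est = MTGBLUP(**kwargs).fit(g, pheno, train_ids)
    return est.predict(predict_ids, return_components=True)


def run_lgc_model1(g, pheno, classes: RegionClasses | None = None,
                   train_ids=None, predict_ids=None, **kwargs) -> PredictionResult:
    """SIG/NON partitioned-kernel model; see :class:`LGCModel1`.

    A precomputed :class:`RegionClasses` may be supplied via ``classes``
    (bypassing LGC estimation) by passing block records instead.
    """
    est = LGCModel1(classes=classes, **kwargs).fit(g, pheno, train_ids)
    return est.predict(predict_ids, return_components=True)


def run_lgc_model2(g, pheno, classes: RegionClasses | None = None,
                   train_ids=None, predict_ids=None, **kwargs) -> PredictionResult:
    """POS/NEG/RES partitioned-kernel model; see :class:`LGCModel2`."""
    est = LGCModel2(classes=classes, **kwargs).fit(g, pheno, train_ids)
    return est.predict(predict_ids, return_components=True)
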