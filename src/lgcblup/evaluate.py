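"""Repeated stratified k-fold cross-validation with accuracy and unbiasedness.

Accuracy is the Pearson correlation between the response (corrected
phenotype or de-regressed proof) and the GEBV of validation individuals;
unbiasedness is the ordinary-least-squares slope of the response on the
GEBV (1 = dispersion-unbiased prediction).  Folds are stratified by
population so each fold preserves the population ratio, and the same fold
assignment is used for every model, making per-repeat comparisons paired.

Per-repeat metrics are computed on the pooled validation predictions of a
repeat's k folds (one r and b per repeat per population), then summarised
as mean ± SD over repeats; a per-fold alternative is available via
``per_fold=True``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import clone

from .data_io import GenotypeMatrix, PhenotypeTable
from .grm import center_genotypes, make_grm
from .ld_partition import partition_genome
from .models import _LGCBase
from .lgc import estimate_lgc

__all__ = ["make_folds", "accuracy_and_bias", "run_cv", "CVMetrics"]


class CVMetrics:
    """Cross-validation results: per-repeat table plus a mean ± SD summary."""

    def __init__(self, per_repeat: pd.DataFrame, folds: dict):
        self.per_repeat = per_repeat
        self.folds = folds

    def summary(self) -> pd.DataFrame:
        g = self.per_repeat.groupby(["model", "pop"], sort=False)
        out = g.agg(r_mean=("r", "mean"), r_sd=("r", "std"),
                    b_mean=("b", "mean"), b_sd=("b", "std"),
                    n_repeats=("r", "size")).reset_index()
        return out

    def paired_differences(self, model_a: str, model_b: str) -> pd.DataFrame:
        """Per-repeat accuracy differences (model_a − model_b), by population."""
        wide = self.per_repeat.pivot_table(
            index=["repeat", "pop"], columns="model", values="r")
        diff = (wide[model_a] - wide[model_b]).rename("r_diff").reset_index()
        return diff


def make_folds(ids, k: int = 10, seed: int | None = None,
               strata=None) -> np.ndarray:
    """Random fold assignment (0..k-1) per individual.

    Folds are disjoint, exhaustive and sized within 1 of each other; when
    ``strata`` (e.g. population labels) is given, each stratum is dealt into
    the folds separately so every fold preserves the stratum ratio.
    """
    ids = np.asarray(ids)
    n = ids.size
    if k > n:
        raise ValueError(f"k={k} folds but only {n} individuals")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    strata = np.zeros(n) if strata is None else np.asarray(strata)
    offset = 0  # rotate fold sizes across strata so totals stay balanced
    for s in pd.unique(strata):
        members = np.flatnonzero(strata == s)
        perm = rng.permutation(members)
        assignment[perm] = (np.arange(perm.size) + offset) % k
        offset += perm.size
    return assignment


def accuracy_and_bias(y_val: np.ndarray, gebv_val: np.ndarray) -> tuple[float, float]:
    """Pearson accuracy r and OLS unbiasedness slope b of y on GEBV."""
    y = np.asarray(y_val, float)
    g = np.asarray(gebv_val, float)
    if y.size < 3:
        raise ValueError("need at least 3 validation pairs")
    if np.ptp(g) == 0:
        raise ValueError("constant GEBV: metrics undefined")
    gc = g - g.mean()
    yc = y - y.mean()
    b = float((gc @ yc) / (gc @ gc))
    denom = np.sqrt((gc @ gc) * (yc @ yc))
    r = float((gc @ yc) / denom) if denom > 0 else np.nan
    return r, b


def run_cv(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    models: dict[str, object],
    k: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    trait: str | None = None,
    stratify: bool = True,
    per_fold: bool = False,
    classes_policy: str = "per-split",
    precompute: bool = True,
) -> CVMetrics:
    """Repeated k-fold CV over a set of models with shared fold assignments.

    ``models`` maps a display name to an (unfitted) estimator; each is cloned
    per fold, fitted on the training individuals and asked for validation
    GEBVs.  Validation phenotypes are never passed to ``fit``.

    ``classes_policy`` controls the partitioned-kernel models: ``"per-split"``
    (default) re-estimates local genetic correlations on every training
    split; ``"fixed"`` estimates them once on the full data — cheaper, but
    region classes then depend on validation phenotypes, which leaks a small
    amount of information.  Heavy shared structures (genome-wide GRM, LD
    partition, per-block GRMs) carry no phenotype information and are always
    precomputed once when ``precompute`` is true.
    """
    trait = trait or pheno.traits[0]
    y_all = pheno.values_for(g.individual_ids, trait)
    phen_ids = g.individual_ids[~np.isnan(y_all)]
    pops = g.population[g.indices_of(phen_ids)]

    models = dict(models)
    if precompute:
        w = center_genotypes(g)
        full_grm = make_grm(w, individual_ids=g.individual_ids)
        shared_partition = None
        shared_block_grms = None
        if any(isinstance(m, _LGCBase) for m in models.values()):
            any_lgc = next(m for m in models.values() if isinstance(m, _LGCBase))
            shared_partition = any_lgc.partition or partition_genome(
                w, max_block_snps=any_lgc.max_block_snps,
                min_snps=any_lgc.min_snps, window=any_lgc.window)
            from .grm import grm_for_partition
            raw = grm_for_partition(
                g, {str(b.block_id): b.snp_indices()
                    for b in shared_partition.blocks})
            shared_block_grms = {int(bid): grm for bid, grm in raw.items()}
        prepared = {}
        for name, m in models.items():
            m = clone(m)
            m.set_params(grm=full_grm)
            if isinstance(m, _LGCBase):
                m.set_params(partition=shared_partition,
                             block_grms=shared_block_grms)
                if classes_policy == "fixed" and m.classes is None:
                    records = estimate_lgc(g, pheno, shared_partition,
                                           trait=trait, train_ids=phen_ids,
                                           tol=m.lgc_tol,
                                           max_iter=m.lgc_max_iter)
                    m.set_params(classes=m._classify(records, shared_partition),
                                 lgc_records=records)
            prepared[name] = m
        models = prepared
    elif classes_policy not in ("per-split", "fixed"):
        raise ValueError("classes_policy must be 'per-split' or 'fixed'")

    rng = np.random.default_rng(seed)
    rows = []
    folds_store = {}
    for rep in range(repeats):
        fold_of = make_folds(phen_ids, k=k,
                             seed=int(rng.integers(0, 2**31 - 1)),
                             strata=pops if stratify else None)
        folds_store[rep] = fold_of
        preds = {name: pd.Series(dtype=float) for name in models}
        for fold in range(k):
            val_ids = phen_ids[fold_of == fold]
            tr_ids = phen_ids[fold_of != fold]
            for name, proto in models.items():
                est = clone(proto)
                try:
                    est.fit(g, pheno, train_ids=tr_ids)
                    ids = est._restrict_candidates(val_ids)
                    gebv = est.predict(ids)
                except Exception as exc:  # noqa: BLE001
                    warnings.warn(f"model {name} failed on repeat {rep} "
                                  f"fold {fold}: {exc}; fold excluded")
                    continue
                preds[name] = pd.concat(
                    [preds[name], pd.Series(gebv, index=ids)])
                if per_fold:
                    _append_metrics(rows, name, rep, fold, pheno, trait, g,
                                    pd.Series(gebv, index=ids))
        if not per_fold:
            for name, series in preds.items():
                if series.empty:
                    continue
                _append_metrics(rows, name, rep, None, pheno, trait, g, series)
    return CVMetrics(pd.DataFrame(rows), folds_store)


def _append_metrics(rows, name, rep, fold, pheno, trait, g, series):
    ids = series.index.to_numpy()
    y = pheno.values_for(ids, trait)
    pops = g.population[g.indices_of(ids)]
    for pop in pd.unique(g.population):
        m = pops == pop
        if m.sum() < 3:
            continue
        try:
            r, b = accuracy_and_bias(y[m], series.to_numpy()[m])
        except ValueError:
            r, b = np.nan, np.nan
        row = {"model": name, "pop": pop, "repeat": rep, "r": r, "b": b}
        if fold is not None:
            row["fold"] = fold
        rows.append(row)
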