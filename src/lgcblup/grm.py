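"""VanRaden genomic relationship matrices from full or region-restricted SNP sets.

The GRM is ``G = W W' / sum_j 2 p_j (1 - p_j)`` with ``w_ij = m_ij - 2 p_j``,
where ``m_ij`` is the additive genotype code and ``p_j`` the counted-allele
frequency on the pooled two-population sample.  Region-restricted GRMs (one
per SIG/NON or POS/NEG/RES class) use region-restricted denominators, so each
kernel is scaled like a standalone VanRaden GRM and its fitted 2×2 covariance
matrix is interpretable as that region-class's genetic covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix

__all__ = [
    "CenteredGenotypes",
    "GRM",
    "center_genotypes",
    "make_grm",
    "grm_for_partition",
    "combine_grms",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_gcta",
    "read_grm_gcta",
]


@dataclass
class CenteredGenotypes:
    """Mean-centered genotype matrix W with its VanRaden denominator.

    ``W[i, j] = m_ij - 2 p_j`` with missing genotypes mean-imputed (set to
    ``2 p_j``, i.e. 0 after centering), and ``denom = sum_j 2 p_j (1 - p_j)``
    over the SNP subset.
    """

    W: np.ndarray
    snp_index: np.ndarray
    denom: float
    freqs: np.ndarray
    chrom: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.W.shape[0]

    @property
    def n_snps(self) -> int:
        return self.W.shape[1]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its SNP-set provenance."""

    values: np.ndarray
    individual_ids: np.ndarray
    snp_set: str = "ALL"
    denom: float = np.nan
    n_snps: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric within 1e-10")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def center_genotypes(
    g: GenotypeMatrix, snp_subset: np.ndarray | None = None
) -> CenteredGenotypes:
    """Center genotype codes to ``w_ij = m_ij - 2 p_j`` on a SNP subset.

    Frequencies are always computed on the combined two-population sample.
    Missing genotypes are mean-imputed (w = 0).  Raises if the subset carries
    no polymorphism (denominator would be zero).
    """
    if snp_subset is None:
        snp_subset = np.arange(g.n_snps)
    snp_subset = np.asarray(snp_subset, dtype=int)
    if snp_subset.size == 0:
        raise ValueError("empty SNP subset")
    p = g.allele_freq()[snp_subset]
    if np.isnan(p).any():
        raise ValueError("subset contains SNPs with no called genotypes")
    codes = g.codes[:, snp_subset]
    W = codes - 2.0 * p
    W[np.isnan(W)] = 0.0  # mean imputation
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("monomorphic SNP subset: VanRaden denominator is zero")
    return CenteredGenotypes(
        W=W, snp_index=snp_subset, denom=denom, freqs=p, chrom=g.chrom[snp_subset]
    )


def make_grm(w: CenteredGenotypes, individual_ids=None, snp_set: str = "ALL") -> GRM:
    """VanRaden GRM ``W W' / denom`` from centered genotypes."""
    if w.n_individuals == 0:
        raise ValueError("no individuals")
    values = (w.W @ w.W.T) / w.denom
    values = (values + values.T) / 2.0  # enforce exact symmetry
    if individual_ids is None:
        individual_ids = np.arange(w.n_individuals)
    return GRM(values=values, individual_ids=np.asarray(individual_ids),
               snp_set=snp_set, denom=w.denom, n_snps=w.n_snps)


def grm_for_partition(
    g: GenotypeMatrix, classes: dict[str, np.ndarray]
) -> dict[str, GRM]:
    """One region-restricted GRM per class of a disjoint, exhaustive SNP partition.

    Each class GRM uses its own denominator.  Empty classes are omitted with a
    warning (downstream models degrade to fewer kernels).
    """
    all_idx = np.concatenate([np.asarray(v, int) for v in classes.values()]) \
        if classes else np.array([], int)
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("class SNP sets overlap")
    out: dict[str, GRM] = {}
    for label, idx in classes.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            warnings.warn(f"region class {label!r} has no SNPs; kernel omitted")
            continue
        out[label] = make_grm(center_genotypes(g, idx),
                              individual_ids=g.individual_ids, snp_set=label)
    return out


def combine_grms(grms: list[GRM], snp_set: str = "ALL") -> GRM:
    """Denominator-weighted combination of GRMs built on disjoint SNP sets.

    For a disjoint exhaustive partition, ``G_ALL = sum_k denom_k G_k / sum_k
    denom_k`` reconstructs the full-panel GRM exactly.
    """
    if not grms:
        raise ValueError("no GRMs to combine")
    denom = sum(x.denom for x in grms)
    values = sum(x.denom * x.values for x in grms) / denom
    return GRM(values=values, individual_ids=grms[0].individual_ids,
               snp_set=snp_set, denom=denom, n_snps=sum(x.n_snps for x in grms))


# -- persistence -------------------------------------------------------------

def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    df = pd.DataFrame(grm.values, index=grm.individual_ids,
                      columns=grm.individual_ids)
    with open(path, "w") as fh:
        fh.write(f"# snp_set={grm.snp_set}\tdenom={grm.denom!r}\tn_snps={grm.n_snps}\n")
        df.to_csv(fh, sep="\t")


def read_grm_tsv(path: str | Path) -> GRM:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(kv.split("=", 1) for kv in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return GRM(values=df.to_numpy(), individual_ids=df.index.to_numpy(),
               snp_set=meta["snp_set"], denom=float(meta["denom"]),
               n_snps=int(meta["n_snps"]))


def write_grm_gcta(grm: GRM, prefix: str | Path) -> None:
    """GCTA binary GRM triplet: float32 lower triangle + ids + SNP counts."""
    prefix = Path(prefix)
    n = grm.n
    tri = grm.values[np.tril_indices(n)]
    Path(f"{prefix}.grm.bin").write_bytes(
        tri.astype("<f4").tobytes())
    Path(f"{prefix}.grm.N.bin").write_bytes(
        np.full(tri.size, grm.n_snps, dtype="<f4").tobytes())
    with open(Path(f"{prefix}.grm.id"), "w") as fh:
        for iid in grm.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_gcta(prefix: str | Path, snp_set: str = "ALL") -> GRM:
    prefix = Path(prefix)
    ids = [line.split("\t")[1].strip()
           for line in Path(f"{prefix}.grm.id").read_text().splitlines()]
    n = len(ids)
    tri = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError("grm.bin size inconsistent with grm.id")
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, -1).T
    nsnp = np.frombuffer(Path(f"{prefix}.grm.N.bin").read_bytes(), dtype="<f4")
    return GRM(values=values, individual_ids=np.array(ids), snp_set=snp_set,
               denom=np.nan, n_snps=int(nsnp[0]) if nsnp.size else 0)
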