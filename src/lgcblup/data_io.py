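"""Genotype, phenotype and block-file I/O plus SNP quality control.

Genotypes travel as :class:`GenotypeMatrix` — an individuals × SNPs matrix of
additive allele counts (0/1/2, ``NaN`` for missing) together with the SNP map
and a two-population label per individual.  The on-disk interfaces are PLINK
1.9 binary (``.bed``/``.bim``/``.fam``), a TSV dosage dialect, a phenotype TSV
(``iid  pop  <trait...>``, missing = ``NA``) and a BED-like block TSV
(``chrom  start_bp  end_bp  block_id``, 1-based inclusive).

The allele counted as 2 is always the first allele of the ``.bim`` line (A1),
and ``p_j`` is the frequency of that counted allele in the pooled sample —
even when it exceeds 0.5 — because the VanRaden centering ``m_ij - 2 p_j``
requires the counted-allele frequency, not the minor-allele frequency.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "DesignSpec",
    "QCReport",
    "read_plink",
    "write_plink",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_blocks",
    "write_blocks",
    "qc_filter",
    "hwe_chisq",
    "quantile_normalize",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1.9, SNP-major

# 2-bit PLINK code -> additive count of the A1 allele (NaN = missing).
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK binary files (bad magic, truncation)."""


class IntegrityError(ValueError):
    """Raised when file dimensions or cross-file identifiers disagree."""


@dataclass
class GenotypeMatrix:
    """Diploid SNP genotypes for the pooled two-population sample.

    Attributes
    ----------
    codes : ndarray of float, shape (n_individuals, n_snps)
        Additive counts of the counted allele, in {0, 1, 2}; NaN = missing.
    snp_ids, chrom, pos_bp : per-SNP map, sorted by (chrom, pos_bp).
    individual_ids : per-individual identifiers, unique.
    population : per-individual population label (at most two distinct).
    alleles : (m, 2) array of counted / other allele, optional.
    """

    codes: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    individual_ids: np.ndarray
    population: np.ndarray
    alleles: np.ndarray | None = None
    _freq_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        for name in ("snp_ids", "chrom", "pos_bp", "individual_ids", "population"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n, m = self.codes.shape
        if len(self.individual_ids) != n or len(self.population) != n:
            raise IntegrityError("individual annotation length != n_individuals")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos_bp) == m):
            raise IntegrityError("SNP annotation length != n_snps")
        if len(np.unique(self.individual_ids)) != n:
            raise IntegrityError("duplicate individual ids")
        if len(self.populations) > 2:
            raise IntegrityError("more than two population labels")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise IntegrityError("genotype codes must be 0/1/2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def populations(self) -> np.ndarray:
        """Distinct population labels, in order of first appearance."""
        _, idx = np.unique(self.population, return_index=True)
        return self.population[np.sort(idx)]

    @property
    def population_index(self) -> np.ndarray:
        """Per-individual 0/1 index into :attr:`populations`."""
        pops = list(self.populations)
        return np.array([pops.index(p) for p in self.population])

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP on the pooled non-missing sample.

        SNPs with no called genotypes get NaN.
        """
        if self._freq_cache is None:
            with np.errstate(invalid="ignore"):
                self._freq_cache = np.nanmean(self.codes, axis=0) / 2.0
        return self._freq_cache

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=0)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving map order."""
        index = np.asarray(index)
        return GenotypeMatrix(
            codes=self.codes[:, index],
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            individual_ids=self.individual_ids,
            population=self.population,
            alleles=None if self.alleles is None else self.alleles[index],
        )

    def indices_of(self, ids) -> np.ndarray:
        """Row indices of the given individual ids (order preserved)."""
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in np.asarray(ids)], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise IntegrityError(f"unknown individual id {exc.args[0]!r}") from exc


@dataclass
class PhenotypeTable:
    """Per-individual trait responses (corrected phenotypes or DRP).

    One row per individual; a ``pop`` label and one column per trait.
    Pre-corrected phenotypes and de-regressed proofs are treated identically
    as unitless response values.  ``commensurable`` declares whether the
    responses of the two populations are measured on the same scale (required
    by the pooled single-trait model).
    """

    frame: pd.DataFrame
    commensurable: bool = True

    def __post_init__(self) -> None:
        if not {"iid", "pop"}.issubset(self.frame.columns):
            raise IntegrityError("phenotype table needs 'iid' and 'pop' columns")
        if self.frame["iid"].duplicated().any():
            raise IntegrityError("duplicate individual in phenotype table")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("iid", "pop")]

    def values_for(self, ids, trait: str | None = None) -> np.ndarray:
        """Responses for the given individuals; NaN where unphenotyped."""
        trait = trait or self.traits[0]
        s = self.frame.set_index("iid")[trait]
        return s.reindex(np.asarray(ids)).to_numpy(dtype=float)


@dataclass
class DesignSpec:
    """Fixed-effect design: default is an intercept (overall mean) per trait."""

    fixed_effects: tuple[str, ...] = ("intercept",)

    def build(self, record_trait: np.ndarray, n_traits: int) -> np.ndarray:
        if tuple(self.fixed_effects) != ("intercept",):
            raise NotImplementedError("only per-trait intercepts are supported")
        X = np.zeros((len(record_trait), n_traits))
        X[np.arange(len(record_trait)), record_trait] = 1.0
        return X


# ---------------------------------------------------------------------------
# PLINK 1.9 binary codec
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1.9 ``.bed``/``.bim``/``.fam`` triplet.

    The counted allele (genotype code 2) is the first ``.bim`` allele (A1).
    The FID column of the ``.fam`` file is used as the population label.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        Path(f"{prefix}.fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phe"], dtype={"fid": str, "iid": str},
    )
    if fam.empty:
        raise IntegrityError(".fam file contains no individuals")
    bim = pd.read_csv(
        Path(f"{prefix}.bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str, "snp": str},
    )
    if bim.empty:
        raise IntegrityError(".bim file contains no SNPs")
    n, m = len(fam), len(bim)

    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"bad .bed magic bytes {raw[:3]!r}")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise IntegrityError(
            f".bed payload is {body.size} bytes; expected {bytes_per_snp * m} "
            f"for {n} individuals x {m} SNPs"
        )
    # unpack 2-bit fields, little-endian within each byte
    mat = body.reshape(m, bytes_per_snp)
    two_bit = np.stack(
        [(mat >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, -1)[:, :n]
    codes = _BED_DECODE[two_bit].T  # individuals x snps

    gm = GenotypeMatrix(
        codes=codes,
        snp_ids=bim["snp"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos_bp=bim["pos"].to_numpy(int),
        individual_ids=fam["iid"].to_numpy(),
        population=fam["fid"].to_numpy(),
        alleles=bim[["a1", "a2"]].to_numpy(),
    )
    return _sort_by_map(gm)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK 1.9 triplet (SNP-major ``.bed``); inverse of read_plink."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.codes.shape
    fam = pd.DataFrame({
        "fid": g.population, "iid": g.individual_ids,
        "pat": 0, "mat": 0, "sex": 0, "phe": -9,
    })
    fam.to_csv(Path(f"{prefix}.fam"), sep="\t", header=False, index=False)
    alleles = g.alleles if g.alleles is not None else np.tile(["A", "B"], (m, 1))
    bim = pd.DataFrame({
        "chrom": g.chrom, "snp": g.snp_ids, "cm": 0, "pos": g.pos_bp,
        "a1": alleles[:, 0], "a2": alleles[:, 1],
    })
    bim.to_csv(Path(f"{prefix}.bim"), sep="\t", header=False, index=False)

    encode = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    two_bit = np.full((m, ((n + 3) // 4) * 4), 0b01, dtype=np.uint8)  # pad=missing
    codes_t = g.codes.T
    for val, bits in encode.items():
        two_bit[:, :n][codes_t == val] = bits
    two_bit[:, :n][np.isnan(codes_t)] = 0b01
    packed = (
        two_bit.reshape(m, -1, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(Path(f"{prefix}.bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _sort_by_map(g: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((g.pos_bp, g.chrom))
    if np.array_equal(order, np.arange(g.n_snps)):
        return g
    return g.take_snps(order)


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_genotype_tsv(path: str | Path | io.IOBase) -> GenotypeMatrix:
    """Read the plain-TSV dosage dialect.

    Layout: columns ``snp  chrom  pos`` followed by one column per individual
    named ``<pop>:<iid>``; cells are 0/1/2 or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    indiv_cols = [c for c in df.columns if c not in ("snp", "chrom", "pos")]
    pops, iids = zip(*(c.split(":", 1) for c in indiv_cols))
    return _sort_by_map(GenotypeMatrix(
        codes=df[list(indiv_cols)].to_numpy(float).T,
        snp_ids=df["snp"].to_numpy(),
        chrom=df["chrom"].to_numpy(),
        pos_bp=df["pos"].to_numpy(int),
        individual_ids=np.array(iids),
        population=np.array(pops),
    ))


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    cols = {"snp": g.snp_ids, "chrom": g.chrom, "pos": g.pos_bp}
    for i, (pop, iid) in enumerate(zip(g.population, g.individual_ids)):
        cols[f"{pop}:{iid}"] = g.codes[i, :]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path | io.IOBase, commensurable: bool = True) -> PhenotypeTable:
    """Read the phenotype TSV (``iid  pop  <trait...>``; missing = NA)."""
    df = pd.read_csv(path, sep="\t", dtype={"iid": str, "pop": str}, na_values=["NA"])
    return PhenotypeTable(df, commensurable=commensurable)


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    p.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_blocks(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a block TSV: ``chrom  start_bp  end_bp  block_id`` (1-based, inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "start_bp", "end_bp", "block_id"}
    if not need.issubset(df.columns):
        raise IntegrityError(f"block file must have columns {sorted(need)}")
    return df


def write_blocks(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-criterion SNP removal counts from :func:`qc_filter`."""

    n_input: int
    n_missing_rate: int
    n_maf: int
    n_hwe: int
    n_retained: int


def hwe_chisq(n0: int, n1: int, n2: int) -> float:
    """Hardy–Weinberg 1-df chi-square p-value from genotype counts.

    Expected counts come from the sample allele frequency.  Monomorphic SNPs
    return p = 1 by convention (HWE is vacuous with one allele).
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("no called genotypes")
    p = (2 * n2 + n1) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(stat, df=1))


def qc_filter(
    g: GenotypeMatrix,
    max_missing_rate: float = 0.01,
    min_maf: float = 0.05,
    hwe_p_floor: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs failing missing-rate, MAF or Hardy–Weinberg thresholds.

    All three tests use the pooled two-population sample.  A SNP is retained
    iff missing rate <= ``max_missing_rate``, min(p, 1-p) >= ``min_maf`` and
    HWE p-value >= ``hwe_p_floor``.  SNP order is preserved; the report counts
    how many SNPs each criterion (alone) would remove.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype panel")
    miss = g.missing_rate()
    freq = g.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    hwe_p = np.empty(g.n_snps)
    for j in range(g.n_snps):
        col = g.codes[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = 1.0
            continue
        hwe_p[j] = hwe_chisq(int((col == 0).sum()), int((col == 1).sum()),
                             int((col == 2).sum()))

    fail_miss = miss > max_missing_rate
    fail_maf = ~(maf >= min_maf)  # NaN maf (all-missing SNP) fails
    fail_hwe = hwe_p < hwe_p_floor
    keep = ~(fail_miss | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("QC removed every SNP: empty panel")
    report = QCReport(
        n_input=g.n_snps,
        n_missing_rate=int(fail_miss.sum()),
        n_maf=int(fail_maf.sum()),
        n_hwe=int(fail_hwe.sum()),
        n_retained=int(keep.sum()),
    )
    return g.take_snps(np.flatnonzero(keep)), report


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Value with rank r (average ranks for ties) maps to the standard-normal
    quantile of ``(r - 0.5) / n`` over the non-missing entries; missing
    entries stay NaN.  The output is rank-identical to the input.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    mask = ~np.isnan(values)
    x = values[mask]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: ranks undefined")
    ranks = stats.rankdata(x, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / x.size)
    return out
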