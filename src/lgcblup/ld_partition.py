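"""Genome partitioning into approximately independent LD blocks.

The splitter emulates the recursive-bisection idea used by block-based local
genetic-correlation methods: starting from one block per chromosome, the
largest block is repeatedly split at the breakpoint that minimises local LD
(summed r² between the SNPs flanking the break), until no block exceeds the
size cap.  Block boundaries never cross chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix
from .grm import CenteredGenotypes

__all__ = [
    "Block",
    "GenomePartition",
    "pairwise_r2",
    "partition_chromosome",
    "partition_genome",
    "partition_from_blocks_table",
]


@dataclass(frozen=True)
class Block:
    """Half-open SNP-index interval [start, stop) on one chromosome.

    Indices refer to columns of the genome-wide (map-ordered) SNP panel.
    """

    chrom: str
    start: int
    stop: int
    block_id: int = -1

    @property
    def n_snps(self) -> int:
        return self.stop - self.start

    def snp_indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class GenomePartition:
    """Ordered, disjoint, exhaustive list of LD blocks."""

    blocks: list[Block]
    n_snps_total: int = 0

    def __post_init__(self) -> None:
        prev_stop: dict[str, int] = {}
        covered = 0
        for b in self.blocks:
            if b.stop <= b.start:
                raise ValueError(f"empty block {b}")
            if b.chrom in prev_stop and b.start != prev_stop[b.chrom]:
                raise ValueError("blocks on a chromosome must tile contiguously")
            prev_stop[b.chrom] = b.stop
            covered += b.n_snps
        if self.n_snps_total == 0:
            self.n_snps_total = covered
        if covered != self.n_snps_total:
            raise ValueError("blocks do not cover every SNP exactly once")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def class_snp_sets(self, assignment: dict[int, str]) -> dict[str, np.ndarray]:
        """Merge block SNP ranges into per-class index sets."""
        out: dict[str, list[np.ndarray]] = {}
        for b in self.blocks:
            out.setdefault(assignment[b.block_id], []).append(b.snp_indices())
        return {k: np.concatenate(v) for k, v in out.items()}

    def to_frame(self, g: GenotypeMatrix) -> pd.DataFrame:
        """Block table with 1-based inclusive bp spans (block-file dialect)."""
        rows = [
            {
                "chrom": b.chrom,
                "start_bp": int(g.pos_bp[b.start]),
                "end_bp": int(g.pos_bp[b.stop - 1]),
                "block_id": b.block_id,
                "n_snps": b.n_snps,
            }
            for b in self.blocks
        ]
        return pd.DataFrame(rows)


def pairwise_r2(w: CenteredGenotypes, i: int, j: int) -> float:
    """Squared Pearson correlation of two centered genotype columns."""
    xi, xj = w.W[:, i], w.W[:, j]
    vi, vj = xi @ xi, xj @ xj
    if vi == 0.0 or vj == 0.0:
        raise ValueError("constant genotype column: r2 undefined")
    r = (xi @ xj) / np.sqrt(vi * vj)
    return float(min(r * r, 1.0))


def _boundary_scores(C: np.ndarray, origin: int, lo: int, hi: int,
                     min_snps: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Score every admissible breakpoint of block [lo, hi).

    A breakpoint at b means sub-blocks [lo, b) and [b, hi); its score is the
    sum of r²(i, j) over i in the last `window` SNPs left of b and j in the
    first `window` SNPs right of b (truncated at the block edges).  C is the
    r² matrix of the whole chromosome, whose first SNP is `origin`.
    """
    cuts = np.arange(lo + min_snps, hi - min_snps + 1)
    scores = np.empty(cuts.size)
    for t, b in enumerate(cuts):
        left = slice(max(lo, b - window) - origin, b - origin)
        right = slice(b - origin, min(hi, b + window) - origin)
        scores[t] = C[left, right].sum()
    return cuts, scores


def partition_chromosome(
    w: CenteredGenotypes,
    chrom: str,
    max_block_snps: int,
    min_snps: int = 25,
    window: int = 50,
) -> GenomePartition:
    """Recursively split one chromosome into LD blocks.

    While any block exceeds ``max_block_snps``, the block with the most SNPs
    is split at the admissible breakpoint (both halves >= ``min_snps``) with
    the minimal windowed cross-LD score; ties go to the leftmost breakpoint.
    """
    if max_block_snps < 2 * min_snps:
        raise ValueError("max_block_snps must be at least 2*min_snps")
    if w.chrom is None:
        raise ValueError("centered genotypes lack chromosome labels")
    idx = np.flatnonzero(np.asarray(w.chrom) == chrom)
    if idx.size == 0:
        raise ValueError(f"no SNPs on chromosome {chrom!r}")
    lo0, hi0 = int(idx[0]), int(idx[-1]) + 1
    if hi0 - lo0 != idx.size:
        raise ValueError("chromosome SNPs are not contiguous in the map")

    X = w.W[:, lo0:hi0]
    sd = X.std(axis=0)
    if (sd == 0.0).any():
        raise ValueError("constant genotype column on chromosome")
    Xs = (X - X.mean(axis=0)) / sd
    C = (Xs.T @ Xs / X.shape[0]) ** 2  # local r² matrix

    blocks: list[tuple[int, int]] = [(lo0, hi0)]
    while True:
        sizes = [hi - lo for lo, hi in blocks]
        order = int(np.argmax(sizes))  # ties: leftmost largest block
        lo, hi = blocks[order]
        if hi - lo <= max_block_snps:
            break
        cuts, scores = _boundary_scores(C, lo0, lo, hi, min_snps, window)
        best = int(cuts[int(np.argmin(scores))])
        blocks[order:order + 1] = [(lo, best), (best, hi)]
        blocks.sort()

    return GenomePartition(
        blocks=[Block(chrom, lo, hi, i) for i, (lo, hi) in enumerate(blocks)],
        n_snps_total=idx.size,
    )


def partition_genome(
    w: CenteredGenotypes,
    max_block_snps: int,
    min_snps: int = 25,
    window: int = 50,
) -> GenomePartition:
    """Apply :func:`partition_chromosome` per chromosome, numbering blocks
    genome-wide in map order.  Chromosomes with fewer than ``min_snps`` SNPs
    are emitted as a single block with a warning.
    """
    chroms = pd.unique(np.asarray(w.chrom))
    all_blocks: list[Block] = []
    for chrom in chroms:
        idx = np.flatnonzero(np.asarray(w.chrom) == chrom)
        if idx.size < min_snps:
            warnings.warn(f"chromosome {chrom!r} has {idx.size} < min_snps SNPs; "
                          "kept as a single block")
            all_blocks.append(Block(str(chrom), int(idx[0]), int(idx[-1]) + 1))
        else:
            part = partition_chromosome(w, str(chrom), max_block_snps,
                                        min_snps, window)
            all_blocks.extend(part.blocks)
    return GenomePartition(
        blocks=[Block(b.chrom, b.start, b.stop, i)
                for i, b in enumerate(all_blocks)],
        n_snps_total=w.n_snps,
    )


def partition_from_blocks_table(g: GenotypeMatrix, table: pd.DataFrame) -> GenomePartition:
    """Build a partition from an externally supplied block table.

    The table uses 1-based inclusive bp spans (block-file dialect); every SNP
    of the panel must fall in exactly one block.
    """
    blocks = []
    for _, row in table.sort_values(["chrom", "start_bp"]).iterrows():
        on = (np.asarray(g.chrom) == str(row["chrom"])) \
            & (g.pos_bp >= row["start_bp"]) & (g.pos_bp <= row["end_bp"])
        idx = np.flatnonzero(on)
        if idx.size == 0:
            warnings.warn(f"block {row['block_id']} contains no SNPs; skipped")
            continue
        blocks.append(Block(str(row["chrom"]), int(idx[0]), int(idx[-1]) + 1,
                            int(row["block_id"])))
    return GenomePartition(blocks=blocks, n_snps_total=g.n_snps)
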