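import warnings

import numpy as np
import pytest

from lgcblup import (Block, GenomePartition, GRM, PhenotypeTable, SimConfig,
                     center_genotypes, make_grm, simulate_dataset)


@pytest.fixture(autouse=True)
def _quiet_reml_warnings():
    """Non-convergence warnings are expected on tiny boundary problems."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="REML did not converge")
        warnings.filterwarnings("ignore", message="LGC fit failed")
        warnings.filterwarnings("ignore", message="region class")
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-population panel with planted ±0.9 / 0 blocks."""
    cfg = SimConfig(
        seed=11, n_per_pop=90, n_pop2=60, n_chromosomes=2, blocks_per_chrom=3,
        snps_per_block=25,
        block_r=np.array([0.9, 0.0, -0.9, 0.0, 0.9, 0.0]),
        block_share=np.array([3.0, 0.5, 2.0, 0.5, 3.0, 0.5]),
    ).resolved()
    return simulate_dataset(cfg) + (cfg,)


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    g, _, _, _ = small_dataset
    return make_grm(center_genotypes(g), individual_ids=g.individual_ids)


@pytest.fixture(scope="session")
def true_partition(small_dataset):
    g, _, _, cfg = small_dataset
    blocks = []
    for b in range(cfg.n_blocks):
        chrom = str(b // cfg.blocks_per_chrom + 1)
        blocks.append(Block(chrom, b * cfg.snps_per_block,
                            (b + 1) * cfg.snps_per_block, b))
    return GenomePartition(blocks, n_snps_total=g.n_snps)
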