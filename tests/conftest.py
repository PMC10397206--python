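import numpy as np
import pytest

from sweeptepop.simulate import SimConfig, simulate_cohort
from sweeptepop.types import GenotypeMatrix, POPULATIONS


def small_config(**overrides) -> SimConfig:
    """A fast cohort: 16 accessions, 0.5 Mbp, 2 sweeps."""
    base = dict(
        n_per_pop=4,
        chrom_length=500_000,
        n_snps=800,
        n_sweeps=2,
        sweep_halfwidth=15_000,
        n_tes=120,
        te_length_range=(200, 2_000),
        n_genes=50,
        gene_length=2_000,
        coverage=8.0,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


def random_matrix(rng, n_acc=8, n_sites=40, missing_rate=0.0) -> GenotypeMatrix:
    """A random genotype matrix for oracle comparisons."""
    n_acc = max(n_acc, 4)
    geno = rng.integers(0, 3, size=(n_acc, n_sites)).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = -1
    accessions = [f"acc{i}" for i in range(n_acc)]
    pops = [POPULATIONS[i % 4] for i in range(n_acc)]
    return GenotypeMatrix(
        accessions=accessions,
        chroms=np.array(["chr1"] * n_sites, dtype=object),
        positions=np.arange(1, n_sites + 1) * 10,
        genotypes=geno,
        population_map=dict(zip(accessions, pops)),
    )
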