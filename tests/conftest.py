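import numpy as np
import pytest

from herdchar import (
    BaldingNicholsSpec,
    GenotypeDataset,
    SampleRecord,
    SnpRecord,
    simulate_balding_nichols,
)


def make_dataset(genotypes, populations, positions=None, chromosomes=None):
    """Build a GenotypeDataset from a plain matrix and per-sample pop labels."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if chromosomes is None:
        chromosomes = ["1"] * m
    snps = [
        SnpRecord(f"snp{j + 1}", chromosomes[j], positions[j])
        for j in range(m)
    ]
    samples = [
        SampleRecord(f"s{i + 1}", populations[i]) for i in range(n)
    ]
    return GenotypeDataset(g, snps, samples)


@pytest.fixture(scope="session")
def bn_three_pops():
    """Moderately differentiated three-population panel reused across tests."""
    return simulate_balding_nichols(
        BaldingNicholsSpec(n_pops=3, n_per_pop=25, n_loci=800, fst=0.15, seed=42)
    )
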