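import numpy as np
import pytest

import kindisperse as kd
from kindisperse.synthetic import GenotypeTable


@pytest.fixture(scope="session")
def default_population():
    """The default synthetic study population (seeded)."""
    return kd.simulate_population(kd.PopulationConfig())


@pytest.fixture(scope="session")
def default_relatedness(default_population):
    """Queller-Goodnight R matrix of the default population."""
    freqs = kd.estimate_allele_frequencies(default_population.genotypes)
    return kd.estimate_relatedness(default_population.genotypes, freqs)


def make_genotypes(records, loci=None):
    """Build a GenotypeTable from {id: {locus: (a1, a2) | None}}."""
    ids = list(records)
    if loci is None:
        loci = sorted({l for g in records.values() for l in g})
    calls = np.full((len(ids), len(loci), 2), -1, dtype=np.int64)
    for i, ind in enumerate(ids):
        for j, locus in enumerate(loci):
            g = records[ind].get(locus)
            if g is not None:
                calls[i, j] = g
    return GenotypeTable(ids, loci, calls)


@pytest.fixture
def tiny_genotypes():
    return make_genotypes
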