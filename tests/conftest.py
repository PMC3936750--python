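import random

import numpy as np
import pytest

from phylosi import GeneRecord, Genome, GenomeSet


def make_genome(genome_id, families, circular=True, strands=None):
    return Genome.from_families(genome_id, families, strands=strands, circular=circular)


def random_genome_shuffled(genome_id, size, rng, circular=True):
    """A genome whose family order is a random permutation of fam0..fam{size-1}."""
    fams = [f"fam{i:04d}" for i in range(size)]
    rng.shuffle(fams)
    strands = [rng.choice("+-") for _ in fams]
    return Genome.from_families(genome_id, fams, strands=strands, circular=circular)


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome_set(rng):
    """Five shuffled genomes over overlapping family vocabularies."""
    genomes = []
    for i in range(5):
        fams = [f"fam{j:04d}" for j in range(10 + 3 * i, 40 + 3 * i)]
        rng.shuffle(fams)
        genomes.append(Genome.from_families(f"g{i}", fams))
    return GenomeSet(genomes)
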