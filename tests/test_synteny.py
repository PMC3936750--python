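"""Synteny-index, gene-content and directed-pairs distance behavior.

Brute-force oracles here are written independently of the library code:
neighborhoods by doubling the gene list, per-gene SI by explicit
occurrence-pair enumeration, GC by direct set counting and DP by listing
adjacencies by hand.
"""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylosi import (
    Genome,
    GenomeSet,
    average_si,
    dp_distance,
    gc_distance,
    gene_si,
    neighborhood,
    si_distance_matrix,
    si_distribution,
)
from phylosi.simulator import hgt_perturb, random_genome

from conftest import make_genome, random_genome_shuffled


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_neighborhood(genome, pos, k):
    fams = [g.family_id for g in genome.genes]
    n = len(fams)
    if genome.circular:
        doubled = fams * 3
        center = n + pos
        window = doubled[center - k: center] + doubled[center + 1: center + k + 1]
        if n <= 2 * k + 1:
            window = [f for i, f in enumerate(fams) if i != pos]
    else:
        window = fams[max(0, pos - k): pos] + fams[pos + 1: pos + k + 1]
    return set(window)


def oracle_gene_si(fam, g1, g2, k):
    occ1 = [i for i, g in enumerate(g1.genes) if g.family_id == fam]
    occ2 = [i for i, g in enumerate(g2.genes) if g.family_id == fam]
    if not occ1 or not occ2:
        return 0.0
    if k == 0:
        return 1.0
    best = 0.0
    for p1 in occ1:
        for p2 in occ2:
            n1 = oracle_neighborhood(g1, p1, k)
            n2 = oracle_neighborhood(g2, p2, k)
            best = max(best, len(n1 & n2) / max(1, min(len(n1), len(n2))))
    return best


def oracle_average_si(g1, g2, k):
    union = {g.family_id for g in g1.genes} | {g.family_id for g in g2.genes}
    return sum(oracle_gene_si(f, g1, g2, k) for f in union) / len(union)


def oracle_gc(g1, g2):
    f1 = {g.family_id for g in g1.genes}
    f2 = {g.family_id for g in g2.genes}
    return (len(f1 - f2) + len(f2 - f1)) / len(f1 | f2)


# ---------------------------------------------------------------------------
# neighborhood
# ---------------------------------------------------------------------------

class TestNeighborhood:
    def test_linear_truncates_at_terminus(self):
        g = make_genome("g", "abcd", circular=False)
        assert neighborhood(g, 0, 1) == {"b"}

    def test_circular_wraps(self):
        g = make_genome("g", "abcd")
        assert neighborhood(g, 0, 1) == {"b", "d"}

    def test_saturates_to_all_other_families(self):
        g = make_genome("g", "abc")
        for pos in range(3):
            assert neighborhood(g, pos, 5) == {"a", "b", "c"} - {g.genes[pos].family_id}

    def test_position_out_of_range(self):
        g = make_genome("g", "abc")
        with pytest.raises(IndexError):
            neighborhood(g, 3, 1)

    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_oracle_on_random_genomes(self, circular, rng):
        for _ in range(20):
            g = random_genome_shuffled("g", rng.randint(3, 30), rng, circular)
            pos = rng.randrange(len(g))
            k = rng.randint(0, 6)
            assert neighborhood(g, pos, k) == oracle_neighborhood(g, pos, k)


# ---------------------------------------------------------------------------
# per-gene and average SI
# ---------------------------------------------------------------------------

class TestGeneSI:
    def test_swapped_tail_pair(self):
        # N1(b) = {a,c}, N2(b) = {a,d}: one of two shared
        g1 = make_genome("g1", "abcd", circular=False)
        g2 = make_genome("g2", "abdc", circular=False)
        assert gene_si("b", g1, g2, 1) == pytest.approx(0.5)

    def test_absent_family_scores_zero(self):
        g1 = make_genome("g1", "abc")
        g2 = make_genome("g2", "def")
        assert gene_si("a", g1, g2, 3) == 0.0

    def test_identical_genomes_score_one(self):
        g = make_genome("g", [f"f{i}" for i in range(20)])
        for k in (0, 1, 5, 9, 15):
            assert gene_si("f3", g, g, k) == 1.0

    def test_k0_shared_family_scores_one_by_convention(self):
        g1 = make_genome("g1", "axc")
        g2 = make_genome("g2", "bxa")
        assert gene_si("x", g1, g2, 0) == 1.0


class TestAverageSI:
    def test_hand_enumerated_linear_pair(self):
        g1 = make_genome("g1", "abcd", circular=False)
        g2 = make_genome("g2", "abdc", circular=False)
        # per-gene: a->1, b->0.5, c->1, d->1; |J| = 4
        assert average_si(g1, g2, 1) == pytest.approx(0.875)

    @pytest.mark.parametrize("circular", [True, False])
    @pytest.mark.parametrize("k", [0, 1, 3, 10])
    def test_identity(self, circular, k, rng):
        g = random_genome_shuffled("g", 25, rng, circular)
        assert average_si(g, g, k) == pytest.approx(1.0)

    def test_disjoint_family_sets(self):
        g1 = make_genome("g1", [f"a{i}" for i in range(10)])
        g2 = make_genome("g2", [f"b{i}" for i in range(10)])
        assert average_si(g1, g2, 4) == 0.0

    def test_symmetry(self, rng):
        g1 = random_genome_shuffled("g1", 20, rng)
        g2 = random_genome_shuffled("g2", 24, rng)
        assert average_si(g1, g2, 3) == pytest.approx(average_si(g2, g1, 3))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(15):
            n1, n2 = rng.randint(4, 40), rng.randint(4, 40)
            overlap = [f"fam{i:04d}" for i in range(rng.randint(2, 15))]
            extra1 = [f"x{i}" for i in range(rng.randint(0, 8))]
            extra2 = [f"y{i}" for i in range(rng.randint(0, 8))]
            f1, f2 = overlap + extra1, overlap + extra2
            rng.shuffle(f1)
            rng.shuffle(f2)
            g1 = make_genome("g1", f1, circular=rng.random() < 0.5)
            g2 = make_genome("g2", f2, circular=rng.random() < 0.5)
            k = rng.randint(0, 5)
            assert average_si(g1, g2, k) == pytest.approx(oracle_average_si(g1, g2, k))

    def test_paralogs_take_best_context(self):
        # family 'p' occurs twice in g1; one copy keeps its context in g2
        g1 = make_genome("g1", ["a", "p", "b", "x", "p", "y"], circular=False)
        g2 = make_genome("g2", ["a", "p", "b", "u", "v", "w"], circular=False)
        assert gene_si("p", g1, g2, 1) == pytest.approx(1.0)

    def test_k0_reduction_equals_gene_content(self, rng):
        for _ in range(10):
            g1 = random_genome_shuffled("g1", rng.randint(5, 30), rng)
            fams = [g.family_id for g in g1.genes][: rng.randint(3, 20)]
            fams += [f"z{i}" for i in range(rng.randint(0, 10))]
            rng.shuffle(fams)
            g2 = make_genome("g2", fams)
            assert 1.0 - average_si(g1, g2, 0) == pytest.approx(gc_distance(g1, g2))


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

class TestSIDistanceMatrix:
    def test_identical_genomes_give_zero_matrix(self):
        g = make_genome("a", [f"f{i}" for i in range(15)])
        gs = GenomeSet(
            Genome(gid, g.genes, True) for gid in ("a", "b", "c")
        )
        D = si_distance_matrix(gs, 3)
        assert np.allclose(D.values, 0.0)

    def test_pairwise_disjoint_genomes_give_ones(self):
        gs = GenomeSet(
            make_genome(f"g{i}", [f"f{i}_{j}" for j in range(8)]) for i in range(4)
        )
        D = si_distance_matrix(gs, 2)
        off = D.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matches_entrywise_oracle(self, small_genome_set):
        D = si_distance_matrix(small_genome_set, 3)
        ids = small_genome_set.ids
        for i, j in itertools.combinations(range(len(ids)), 2):
            expected = 1.0 - oracle_average_si(
                small_genome_set[ids[i]], small_genome_set[ids[j]], 3
            )
            assert D.values[i, j] == pytest.approx(expected)

    def test_symmetric_zero_diagonal_unit_interval(self, small_genome_set):
        D = si_distance_matrix(small_genome_set, 5)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0)
        assert ((D.values >= 0) & (D.values <= 1)).all()


# ---------------------------------------------------------------------------
# GC and DP baselines
# ---------------------------------------------------------------------------

class TestGeneContent:
    def test_private_fraction(self):
        assert gc_distance(make_genome("a", "abc"), make_genome("b", "bcd")) == 0.5

    def test_identical_and_disjoint_extremes(self):
        a = make_genome("a", "abcde")
        assert gc_distance(a, a) == 0.0
        assert gc_distance(a, make_genome("b", "fghij")) == 1.0

    def test_matches_oracle(self, rng):
        for _ in range(10):
            g1 = random_genome_shuffled("g1", rng.randint(3, 25), rng)
            g2 = random_genome_shuffled("g2", rng.randint(3, 25), rng)
            assert gc_distance(g1, g2) == pytest.approx(oracle_gc(g1, g2))


class TestDirectedPairs:
    def test_identical_genomes(self):
        g = make_genome("g", "abcde", strands="++-+-")
        assert dp_distance(g, g) == 0.0

    def test_no_shared_adjacency(self):
        g1 = make_genome("g1", "abcdef", circular=False)
        g2 = make_genome("g2", "acebdf", circular=False)
        # permutation chosen to share no ordered adjacency
        assert dp_distance(g1, g2) == 1.0

    def test_shared_pair_with_private_tails(self):
        g1 = make_genome("g1", "abc", strands="+++", circular=False)
        g2 = make_genome("g2", "abd", strands="+++", circular=False)
        assert dp_distance(g1, g2) == 0.0

    def test_reverse_complement_adjacency_matches(self):
        # (a+, b+) in g1 equals (b-, a-) read from the other strand in g2
        g1 = make_genome("g1", "ab", strands="++", circular=False)
        g2 = make_genome("g2", "ba", strands="--", circular=False)
        assert dp_distance(g1, g2) == 0.0

    def test_orientation_flip_breaks_match(self):
        g1 = make_genome("g1", "ab", strands="++", circular=False)
        g2 = make_genome("g2", "ab", strands="+-", circular=False)
        assert dp_distance(g1, g2) == 1.0

    def test_symmetry(self, rng):
        g1 = random_genome_shuffled("g1", 15, rng)
        g2 = random_genome_shuffled("g2", 15, rng)
        assert dp_distance(g1, g2) == pytest.approx(dp_distance(g2, g1))


# ---------------------------------------------------------------------------
# SI distribution
# ---------------------------------------------------------------------------

class TestSIDistribution:
    def test_identical_genomes_mass_at_one(self):
        g = make_genome("g", [f"f{i}" for i in range(12)])
        d = si_distribution(g, g, 3)
        assert d.counts == {1.0: 12}

    def test_disjoint_genomes_mass_at_zero(self):
        d = si_distribution(make_genome("a", "abc"), make_genome("b", "def"), 2)
        assert d.counts == {0.0: 6}

    def test_mass_and_mean_consistency(self, rng):
        for _ in range(10):
            g1 = random_genome_shuffled("g1", rng.randint(5, 30), rng)
            g2 = random_genome_shuffled("g2", rng.randint(5, 30), rng)
            k = rng.randint(0, 5)
            d = si_distribution(g1, g2, k)
            assert sum(d.counts.values()) == d.union_size
            assert d.mean == pytest.approx(average_si(g1, g2, k))


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@st.composite
def genome_pairs(draw):
    alphabet = [f"f{i}" for i in range(12)]
    f1 = draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=15))
    f2 = draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=15))
    c1 = draw(st.booleans())
    c2 = draw(st.booleans())
    return make_genome("g1", f1, circular=c1), make_genome("g2", f2, circular=c2)


@settings(max_examples=60, derandomize=True)
@given(genome_pairs(), st.integers(min_value=0, max_value=5))
def test_average_si_bounded_symmetric_and_oracle_consistent(pair, k):
    g1, g2 = pair
    s = average_si(g1, g2, k)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(average_si(g2, g1, k))
    assert s == pytest.approx(oracle_average_si(g1, g2, k))


def test_perturbation_rate_ordering():
    """Mean SI decreases with the relocation rate (30 replicates per rate)."""
    k = 5
    means = {}
    for P in (0.1, 0.4):
        vals = []
        for rep in range(30):
            base = random_genome(f"g{rep}", 120)
            pert = hgt_perturb(base, P, seed=1000 + rep)
            vals.append(average_si(base, pert, k))
        means[P] = np.mean(vals)
    assert means[0.1] > means[0.4]
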