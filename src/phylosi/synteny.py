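"""Synteny-index, gene-content and directed-pairs genome distances.

The synteny index (SI) of a gene shared by two genomes is the normalized
overlap between its k-neighborhoods (the gene families at most k positions
up- or downstream) in the two genomes.  Averaged over the union gene-family
set J of a genome pair it yields a similarity in [0, 1] that decays as
gene gain, loss and horizontal transfer scramble gene order; 1 - SI is the
distance fed to neighbor joining.

Two classic whole-genome baselines are provided for comparison: the
gene-content (GC) distance (fraction of the union private to one genome,
exactly the k = 0 limit of the SI distance) and the directed-pairs (DP)
distance built from shared co-oriented adjacent gene pairs.

Normalization of the per-gene SI divides the neighborhood intersection by
min(|N_k in G1|, |N_k in G2|) (floor 1), which makes SI(G, G) = 1 hold for
linear genomes and genomes shorter than 2k + 1; for circular genomes of
length >= 2k + 1 it coincides with the natural 2k denominator.  For a
family with several copies in a genome the per-gene SI is the maximum over
occurrence pairs, and J counts each family once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import DistanceMatrix, Genome, GenomeSet

DEFAULT_K = 10

__all__ = [
    "DEFAULT_K",
    "SIDistribution",
    "neighborhood",
    "gene_si",
    "average_si",
    "si_distance_matrix",
    "gc_distance",
    "dp_distance",
    "si_distribution",
]


def neighborhood(G: Genome, position: int, k: int) -> frozenset[str]:
    """Family set within k positions of ``position``, excluding the focal gene.

    Circular genomes wrap around; linear genomes truncate at the termini.
    When the genome has at most 2k + 1 genes the neighborhood saturates to
    every other position.
    """
    n = len(G)
    if not 0 <= position < n:
        raise IndexError(f"position {position} out of range for genome of length {n}")
    if k < 0:
        raise ValueError("k must be >= 0")
    if G.circular:
        if n <= 2 * k + 1:
            idx = [i for i in range(n) if i != position]
        else:
            idx = [(position + d) % n for d in range(-k, k + 1) if d != 0]
    else:
        lo, hi = max(0, position - k), min(n - 1, position + k)
        idx = [i for i in range(lo, hi + 1) if i != position]
    return frozenset(G.genes[i].family_id for i in idx)


def _positions(G: Genome) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i, rec in enumerate(G.genes):
        pos.setdefault(rec.family_id, []).append(i)
    return pos


def _pair_neighborhoods(G: Genome, k: int) -> dict[str, list[frozenset[str]]]:
    """Neighborhood sets of every occurrence, keyed by family."""
    out: dict[str, list[frozenset[str]]] = {}
    for fam, plist in _positions(G).items():
        out[fam] = [neighborhood(G, p, k) for p in plist]
    return out


def _si_from_neighborhoods(
    nbrs1: list[frozenset[str]], nbrs2: list[frozenset[str]]
) -> float:
    best = 0.0
    for a in nbrs1:
        for b in nbrs2:
            denom = max(1, min(len(a), len(b)))
            s = len(a & b) / denom
            if s > best:
                best = s
    return best


def gene_si(family: str, G1: Genome, G2: Genome, k: int) -> float:
    """Per-gene synteny index of one family between two genomes.

    0 when the family is absent from either genome; at k = 0 a shared
    family scores 1 by convention (neighborhoods are empty).
    """
    p1, p2 = _positions(G1), _positions(G2)
    if family not in p1 or family not in p2:
        return 0.0
    if k == 0:
        return 1.0
    n1 = [neighborhood(G1, p, k) for p in p1[family]]
    n2 = [neighborhood(G2, p, k) for p in p2[family]]
    return _si_from_neighborhoods(n1, n2)


def average_si(G1: Genome, G2: Genome, k: int = DEFAULT_K) -> float:
    """Average synteny index over the union gene-family set.

    Equals 1 for identical genomes and 0 for genomes with disjoint family
    sets; at k = 0 it reduces to the shared-family fraction |F1 ∩ F2|/|F1 ∪ F2|.
    """
    f1, f2 = G1.families, G2.families
    union = f1 | f2
    shared = f1 & f2
    if not union:
        raise ValueError("both genomes are empty")
    if k == 0:
        return len(shared) / len(union)
    nb1 = _pair_neighborhoods(G1, k)
    nb2 = _pair_neighborhoods(G2, k)
    total = 0.0
    for fam in shared:
        total += _si_from_neighborhoods(nb1[fam], nb2[fam])
    return total / len(union)


def si_distance_matrix(gs: GenomeSet, k: int = DEFAULT_K) -> DistanceMatrix:
    """Pairwise SI distance matrix, entry (i, j) = 1 - average_si(G_i, G_j, k)."""
    ids = gs.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 genomes")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - average_si(gs[ids[i]], gs[ids[j]], k)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids, D)


def gc_distance(G1: Genome, G2: Genome) -> float:
    """Gene-content distance: fraction of the union private to one genome."""
    f1, f2 = G1.families, G2.families
    union = f1 | f2
    if not union:
        raise ValueError("both genomes are empty")
    return len(f1 ^ f2) / len(union)


def _adjacencies(G: Genome) -> set[tuple[str, str, str, str]]:
    """Canonical directed, oriented adjacencies of a genome.

    An adjacency (x, sx) -> (y, sy) is equivalent to its reverse-complement
    (y, -sy) -> (x, -sx) (orientation is defined only up to reading
    direction); the lexicographically smaller tuple represents the pair.
    Unknown strands are treated as +.
    """
    flip = {"+": "-", "-": "+"}
    out = set()
    n = len(G)
    pairs = range(n if G.circular else n - 1)
    for i in pairs:
        a, b = G.genes[i], G.genes[(i + 1) % n]
        sa = a.strand if a.strand in flip else "+"
        sb = b.strand if b.strand in flip else "+"
        fwd = (a.family_id, sa, b.family_id, sb)
        rev = (b.family_id, flip[sb], a.family_id, flip[sa])
        out.add(min(fwd, rev))
    return out


def dp_distance(G1: Genome, G2: Genome) -> float:
    """Directed-pairs distance from shared co-oriented adjacent gene pairs.

    Similarity is the number of adjacencies common to both genomes divided
    by the number of adjacencies whose two families are shared, averaged
    over the two directions of comparison; the distance is 1 - similarity.
    A side with no comparable adjacency contributes similarity 0.
    """
    a1, a2 = _adjacencies(G1), _adjacencies(G2)
    f1, f2 = G1.families, G2.families
    shared = a1 & a2
    denom1 = sum(1 for x, _, y, _ in a1 if x in f2 and y in f2)
    denom2 = sum(1 for x, _, y, _ in a2 if x in f1 and y in f1)
    r1 = len(shared) / denom1 if denom1 else 0.0
    r2 = len(shared) / denom2 if denom2 else 0.0
    return 1.0 - 0.5 * (r1 + r2)


@dataclass
class SIDistribution:
    """Histogram f(SI) of per-gene SI values over a pair's union gene set."""

    pair: tuple[str, str]
    counts: dict[float, int]
    union_size: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.union_size:
            raise ValueError("histogram mass must equal the union-set size")
        if any(not 0.0 <= x <= 1.0 for x in self.counts):
            raise ValueError("SI values must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return sum(x * c for x, c in self.counts.items()) / self.union_size

    def support_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.array(sorted(self.counts))
        ws = np.array([self.counts[x] for x in xs], dtype=float)
        return xs, ws / ws.sum()

    def to_tsv(self, path) -> None:
        import pandas as pd

        xs = sorted(self.counts)
        pd.DataFrame({"si_value": xs, "count": [self.counts[x] for x in xs]}).to_csv(
            path, sep="\t", index=False
        )


def si_distribution(G1: Genome, G2: Genome, k: int = DEFAULT_K) -> SIDistribution:
    """Per-gene SI histogram over the union family set of a genome pair.

    The mean of the distribution equals ``average_si(G1, G2, k)`` exactly;
    families private to one genome contribute mass at SI = 0.
    """
    f1, f2 = G1.families, G2.families
    union = f1 | f2
    shared = f1 & f2
    counts: dict[float, int] = {}
    if k == 0:
        values = [1.0 if fam in shared else 0.0 for fam in union]
    else:
        nb1 = _pair_neighborhoods(G1, k)
        nb2 = _pair_neighborhoods(G2, k)
        values = [
            _si_from_neighborhoods(nb1[fam], nb2[fam]) if fam in shared else 0.0
            for fam in union
        ]
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return SIDistribution((G1.genome_id, G2.genome_id), counts, len(union))
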