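"""Benchmark simulator: Yule species trees and gene gain/loss/HGT evolution.

The generative model treats gene gain and loss as time-dependent Markovian
events along a species tree.  The tree topology comes from the Yule
pure-birth process (a uniformly chosen extant lineage splits at each step);
edge lengths are i.i.d. exponential with rate ``edge_rate``, representing
waiting times of the event process.  Along each edge a Poisson number of
events occurs (rate per gene per unit branch length, scaled by the current
genome size); each event is a gene gain with probability ``p_hgt`` — a
brand-new family inserted at a uniform position, i.e. horizontal
acquisition from outside the sampled taxa — and otherwise a loss of a
uniformly chosen gene.

A separate pairwise perturbation operator relocates each gene
independently with probability P (excise + uniform reinsertion), which
randomizes neighborhoods while preserving gene content.  It isolates the
synteny signal and drives the SI-versus-k calibration curves.

Uniform random unrooted binary trees (sequential edge attachment) live in
:mod:`phylosi.tree_compare`; they are re-exported here for convenience.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, asdict

import dendropy
import numpy as np
import pandas as pd

from .genome_io import GeneRecord, Genome, GenomeSet
from .synteny import average_si, si_distance_matrix
from .treebuild import neighbor_joining
from .tree_compare import random_binary_tree, rf_similarity

__all__ = [
    "SimConfig",
    "yule_tree",
    "evolve_genomes",
    "hgt_perturb",
    "random_genome",
    "si_vs_k_curve",
    "accuracy_vs_k_experiment",
    "random_binary_tree",
]


@dataclass
class SimConfig:
    """All simulator knobs for one benchmark run.

    n_taxa: number of leaf genomes.
    edge_rate: exponential rate of edge lengths (mean length 1/edge_rate).
    event_rate: gain/loss events per gene per unit branch length.
    p_hgt: probability an event is a gain (new family); 1 - p_hgt a loss.
    root_size: gene count of the ancestral genome.
    seed: master RNG seed.
    ultrametric: enforce a molecular clock on the Yule tree instead of
        i.i.d. exponential edge lengths (off by default).
    """

    n_taxa: int = 100
    edge_rate: float = 1.0
    event_rate: float = 0.1
    p_hgt: float = 0.5
    root_size: int = 500
    seed: int = 0
    ultrametric: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p_hgt <= 1:
            raise ValueError("p_hgt must be in [0, 1]")
        if self.root_size < 1:
            raise ValueError("root_size must be >= 1")
        if self.edge_rate <= 0:
            raise ValueError("edge_rate must be > 0")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


def yule_tree(n_taxa: int, edge_rate: float = 1.0, seed: int | None = None,
              ultrametric: bool = False) -> dendropy.Tree:
    """Rooted Yule-process species tree with exponential edge lengths.

    The topology grows by splitting a uniformly chosen extant lineage
    until ``n_taxa`` leaves exist.  By default every edge independently
    draws an Exp(edge_rate) length; with ``ultrametric`` the Yule waiting
    times themselves set node heights so all leaves are contemporaneous.
    Leaves are labeled t1..tN in creation order.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    tips = [dendropy.Node(), dendropy.Node()]
    for t in tips:
        root.add_child(t)
    split_time = {id(root): 0.0}
    now = 0.0
    while len(tips) < n_taxa:
        now += float(rng.exponential(1.0 / (len(tips) * edge_rate)))
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        split_time[id(node)] = now
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        tips.extend([a, b])
    present = now + float(rng.exponential(1.0 / (n_taxa * edge_rate)))

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon = tns.get_taxon(label)

    if ultrametric:
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            top = split_time[id(nd.parent_node)]
            nd.edge.length = (present - top) if nd.is_leaf() else split_time[id(nd)] - top
    else:
        edges = [nd.edge for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        lengths = rng.exponential(1.0 / edge_rate, size=len(edges))
        for e, ln in zip(edges, lengths):
            e.length = float(ln)
    tree.is_rooted = True
    return tree


def evolve_genomes(tree: dendropy.Tree, config: SimConfig) -> GenomeSet:
    """Evolve genomes down a rooted species tree under gain/loss events.

    The root genome is ``root_size`` fresh families in order.  On each
    edge the event count is Poisson(event_rate * length * genome size at
    the top of the edge); events apply sequentially — a gain (probability
    p_hgt) inserts a brand-new family at a uniform position, a loss
    deletes a uniform position.  Returns leaf genomes keyed by leaf label.
    A genome shrinking to zero genes aborts: the loss rate needs
    recalibration (heavy shrinkage also voids the synteny signal).
    """
    rng = np.random.default_rng(config.seed)
    counter = [config.root_size]

    root_genome = [f"fam{i:06d}" for i in range(config.root_size)]
    out: dict[str, list[str]] = {}

    def descend(node: dendropy.Node, genome: list[str]) -> None:
        for child in node.child_nodes():
            g = list(genome)
            length = child.edge.length or 0.0
            n_events = int(rng.poisson(config.event_rate * length * len(g)))
            for _ in range(n_events):
                if rng.random() < config.p_hgt:
                    fam = f"hgt{counter[0]:06d}"
                    counter[0] += 1
                    pos = int(rng.integers(len(g) + 1))
                    g.insert(pos, fam)
                else:
                    if len(g) <= 1:
                        raise RuntimeError(
                            "a simulated genome shrank to zero genes; lower "
                            "event_rate or raise p_hgt (the gain/loss rates "
                            "need recalibration)"
                        )
                    pos = int(rng.integers(len(g)))
                    del g[pos]
            if child.is_leaf():
                out[child.taxon.label] = g
            else:
                descend(child, g)

    descend(tree.seed_node, root_genome)
    return GenomeSet(
        Genome(label, tuple(GeneRecord(f) for f in fams), circular=True)
        for label, fams in out.items()
    )


def random_genome(genome_id: str, size: int, circular: bool = True) -> Genome:
    """A genome of ``size`` distinct families in order (the simulator's root)."""
    return Genome.from_families(
        genome_id, (f"fam{i:06d}" for i in range(size)), circular=circular
    )


def hgt_perturb(G: Genome, P: float, seed: int | None = None) -> Genome:
    """Relocate each gene independently with probability P.

    A selected gene is excised and reinserted at a uniformly random
    position, randomizing its neighborhood while leaving the family
    multiset untouched — a pure synteny perturbation emulating transfer
    into a new chromosomal context.
    """
    if not 0 <= P <= 1:
        raise ValueError("P must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(G.genes)
    selected = [g for g, pick in zip(G.genes, rng.random(len(genes)) < P) if pick]
    for rec in selected:
        genes.remove(rec)
        pos = int(rng.integers(len(genes) + 1))
        genes.insert(pos, rec)
    return Genome(G.genome_id + "_perturbed", tuple(genes), G.circular)


def si_vs_k_curve(
    genome_size: int,
    P_values,
    k_values,
    replicates: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean SI between a genome and its P-perturbed copy, across k.

    For each perturbation rate P and replicate, a fresh genome of
    ``genome_size`` genes is relocated gene-by-gene with probability P and
    the average SI against the original is recorded for every k.  The
    resulting curves rise with k (saturating at 1 as k approaches the
    genome scale) and fall with P at fixed k — the calibration used to
    pick the working neighborhood radius.
    """
    if genome_size < 2 * max(k_values) + 1:
        raise ValueError("genome_size must be at least 2*max(k)+1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for P in P_values:
        for rep, child in enumerate(ss.spawn(replicates)):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            base = random_genome(f"g{rep}", genome_size)
            pert = hgt_perturb(base, P, seed=sub_seed)
            for k in k_values:
                rows.append((P, k, rep, average_si(base, pert, k)))
    df = pd.DataFrame(rows, columns=["P", "k", "replicate", "si"])
    return (
        df.groupby(["P", "k"], as_index=False)["si"].mean().rename(columns={"si": "mean_si"})
    )


def accuracy_vs_k_experiment(
    hgt_rates,
    k_values,
    n_taxa: int = 100,
    genome_size: int = 500,
    replicates: int = 10,
    edge_rate: float = 1.0,
    p_hgt: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Reconstruction accuracy (RF similarity to the model tree) versus k.

    Per replicate: simulate a Yule tree and leaf genomes at the given
    event rate, build the SI distance matrix for each k, reconstruct by
    neighbor joining, and score against the (unrooted) model tree.  Means
    are tabulated per (rate, k).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rate in hgt_rates:
        for rep, child in enumerate(ss.spawn(replicates)):
            s1, s2 = (int(x % (2**31)) for x in child.generate_state(2))
            tree = yule_tree(n_taxa, edge_rate, seed=s1)
            cfg = SimConfig(
                n_taxa=n_taxa,
                edge_rate=edge_rate,
                event_rate=rate,
                p_hgt=p_hgt,
                root_size=genome_size,
                seed=s2,
            )
            gs = evolve_genomes(tree, cfg)
            model = tree.clone(depth=1)
            model.is_rooted = False
            for k in k_values:
                D = si_distance_matrix(gs, k)
                rec = neighbor_joining(D)
                rows.append((rate, k, rep, rf_similarity(rec, model)))
    df = pd.DataFrame(rows, columns=["rate", "k", "replicate", "rf_similarity"])
    return (
        df.groupby(["rate", "k"], as_index=False)["rf_similarity"]
        .mean()
        .rename(columns={"rf_similarity": "mean_rf_similarity"})
    )
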