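"""SI-distribution bootstrap: branch supports for synteny-index trees.

Instead of resampling alignment columns (there is no alignment), the
bootstrap resamples the units the SI distance averages over: for every
genome pair the per-gene SI histogram f(SI) over the union gene set J is
resampled with replacement (|J| draws, weighted by the histogram counts),
giving a perturbed "bootstrap SI matrix" per replicate.  Neighbor-joining
trees built from the replicate matrices vote on each internal edge of the
point-estimate tree; the percentage of replicates containing an edge's
bipartition is its support.  Edges below a support threshold (80% by
convention) can be contracted into polytomies.
"""

from __future__ import annotations

import logging
import warnings

import dendropy
import numpy as np

from .genome_io import DistanceMatrix, GenomeSet
from .synteny import DEFAULT_K, si_distance_matrix, si_distribution
from .treebuild import bipartitions, leaf_labels, neighbor_joining

logger = logging.getLogger(__name__)

__all__ = [
    "bootstrap_matrix",
    "bootstrap_support",
    "collapse_low_support",
    "split_supports",
]


def _pair_rng(master_seed: int, replicate: int, pair_index: int) -> np.random.Generator:
    # one independent, reproducible stream per (replicate, pair)
    return np.random.default_rng([master_seed & 0x7FFFFFFF, replicate, pair_index])


def bootstrap_matrix(
    gs: GenomeSet,
    k: int = DEFAULT_K,
    rng_seed: int = 0,
    replicate: int = 0,
    boot_samples: int | None = None,
    distributions: dict | None = None,
) -> DistanceMatrix:
    """One bootstrap resample of the SI distance matrix.

    For each unordered genome pair, |J| values (or ``boot_samples``) are
    drawn from the pair's SI histogram with probability proportional to
    the histogram counts; the matrix entry is 1 minus their mean.
    Precomputed ``distributions`` (pair-index keyed) avoid recomputing the
    histograms across replicates.
    """
    ids = gs.ids
    if len(ids) < 4:
        raise ValueError("bootstrap needs at least 4 genomes")
    n = len(ids)
    D = np.zeros((n, n))
    pair_index = 0
    for i in range(n):
        for j in range(i + 1, n):
            if distributions is not None and pair_index in distributions:
                dist = distributions[pair_index]
            else:
                dist = si_distribution(gs[ids[i]], gs[ids[j]], k)
                if distributions is not None:
                    distributions[pair_index] = dist
            xs, ws = dist.support_and_weights()
            n_samples = boot_samples or dist.union_size
            rng = _pair_rng(rng_seed, replicate, pair_index)
            sample = rng.choice(xs, size=n_samples, p=ws)
            D[i, j] = D[j, i] = 1.0 - float(sample.mean())
            pair_index += 1
    return DistanceMatrix(ids, D)


def bootstrap_support(
    gs: GenomeSet,
    k: int = DEFAULT_K,
    replicates: int = 100,
    rng_seed: int = 0,
    boot_samples: int | None = None,
) -> dendropy.Tree:
    """Point-estimate SI tree annotated with bootstrap supports.

    Builds the NJ tree from the plug-in SI distance matrix, then
    ``replicates`` NJ trees from bootstrap matrices; each internal edge of
    the point tree is labeled with the integer percentage of replicates
    whose tree contains the same bipartition.  Fully reproducible from
    ``rng_seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = neighbor_joining(si_distance_matrix(gs, k))
    target = bipartitions(point)
    votes = {split: 0 for split in target}
    distributions: dict = {}
    for rep in range(replicates):
        B = bootstrap_matrix(
            gs, k, rng_seed=rng_seed, replicate=rep,
            boot_samples=boot_samples, distributions=distributions,
        )
        rep_splits = bipartitions(neighbor_joining(B))
        for split in target:
            if split in rep_splits:
                votes[split] += 1

    labels = leaf_labels(point)
    anchor = labels[0]
    full = frozenset(labels)
    nleaf = len(labels)
    below: dict[int, frozenset[str]] = {}
    for node in point.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        side = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = side
        if node.parent_node is None:
            continue
        canon = side if anchor not in side else full - side
        if 2 <= len(canon) <= nleaf - 2 and canon in votes:
            node.label = str(int(round(100.0 * votes[canon] / replicates)))
    return point


def split_supports(tree: dendropy.Tree) -> dict[frozenset[str], int | None]:
    """Map each informative split to its integer support (None if unlabeled)."""
    labels = leaf_labels(tree)
    anchor, full, n = labels[0], frozenset(labels), len(labels)
    out: dict[frozenset[str], int | None] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        side = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = side
        if node.parent_node is None:
            continue
        canon = side if anchor not in side else full - side
        if 2 <= len(canon) <= n - 2:
            try:
                out[canon] = int(float(node.label)) if node.label else None
            except (TypeError, ValueError):
                out[canon] = None
    return out


def collapse_low_support(tree: dendropy.Tree, threshold: float = 80.0) -> dendropy.Tree:
    """Contract internal edges with support below ``threshold`` into polytomies.

    Internal edges without a support label are treated as support 0 (with
    a warning).  The leaf set is unchanged; raising the threshold can only
    remove further edges.
    """
    t = tree.clone(depth=1)
    labels = leaf_labels(t)
    n = len(labels)
    to_collapse = []
    unlabeled = 0
    for node in t.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        size_below = len([lf for lf in node.leaf_iter()])
        if size_below < 2 or size_below > n - 2:
            continue
        try:
            support = float(node.label)
        except (TypeError, ValueError):
            support = 0.0
            unlabeled += 1
        if support < threshold:
            to_collapse.append(node)
    if unlabeled:
        warnings.warn(
            f"{unlabeled} internal edge(s) lacked a support label; treated as support 0",
            stacklevel=2,
        )
    for node in to_collapse:
        node.edge.collapse()
    return t
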