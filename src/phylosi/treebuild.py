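"""Neighbor-joining reconstruction and Newick tree plumbing.

Trees are held as :class:`dendropy.Tree` objects throughout the package;
reconstruction output is unrooted (trifurcating seed node).  Neighbor
joining follows the classic Saitou–Nei Q-criterion with two deterministic
conventions: ties in the Q matrix are broken by the lexicographic order of
each cluster's smallest leaf label, and negative branch lengths are
clamped to zero (the total clamped mass is logged).  Determinism matters
here — bootstrap replicates must be reproducible from a seed alone.
"""

from __future__ import annotations

import logging
import math

import dendropy
import numpy as np

from .genome_io import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "neighbor_joining",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "internal_edges",
    "leaf_labels",
]


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Informative splits of an (un)rooted tree as canonical label sets.

    Each internal edge separates the leaves into two sides; the side NOT
    containing the lexicographically smallest leaf label represents the
    split.  Only informative splits (both sides of size >= 2) are returned,
    so the result is empty for a star tree and has n - 3 elements for a
    fully resolved binary tree.
    """
    labels = leaf_labels(tree)
    n = len(labels)
    anchor = labels[0]
    below: dict[int, frozenset[str]] = {}
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        side = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = side
        if node.parent_node is None:
            continue
        canon = side if anchor not in side else frozenset(labels) - side
        if 2 <= len(canon) <= n - 2:
            splits.add(canon)
    return splits


def internal_edges(tree: dendropy.Tree) -> tuple[int, list[frozenset[str]]]:
    """Count (and list) the informative internal edges of a tree.

    A fully resolved unrooted binary tree on n leaves has exactly n - 3.
    """
    splits = sorted(bipartitions(tree), key=lambda s: sorted(s))
    return len(splits), splits


def _clamp(x: float, clamped: list[float]) -> float:
    if x < 0.0:
        clamped[0] -= x
        return 0.0
    return x


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a distance matrix.

    Returns an unrooted binary tree (trifurcating seed node) whose leaf
    set equals the matrix taxa.  Tie-breaking and negative-branch handling
    are deterministic; permuting the input taxon order changes the result
    only up to isomorphism.
    """
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(D.values, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance matrix has non-finite entries")

    tns = dendropy.TaxonNamespace(D.taxa)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for label in D.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
        reps.append(label)

    clamped = [0.0]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        i, j = min(
            ((int(a), int(b)) for a, b in ties if a < b),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))),
        )
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li, clamped), _clamp(lj, clamped)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]
        reps = [reps[x] for x in keep] + [min(reps[i], reps[j])]

    seed = dendropy.Node()
    if len(nodes) == 3:
        la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for nd, ln in zip(nodes, (la, lb, lc)):
            seed.add_child(nd)
            nd.edge.length = _clamp(ln, clamped)
    if clamped[0] > 0:
        logger.info("neighbor_joining: clamped %.6g of negative branch length", clamped[0])

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize to Newick (supports as internal-node labels); optionally to a file."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; internal-node labels are kept (bootstrap supports)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths (branch-length weighted), labels sorted."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = leaf_labels(tree)
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return labels, M
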