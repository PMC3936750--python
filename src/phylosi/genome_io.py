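"""Gene-order genome containers and file IO.

A genome is modelled at gene resolution: an ordered sequence of gene
records, each carrying an ortholog-family identifier (a COG-like token
shared across genomes) and a strand.  Nucleotide coordinates are never
used — position means rank in the gene order.  Prokaryotic chromosomes
are circular by default; linearity is an explicit per-genome flag.

The native on-disk format is a TSV with columns
``genome_id, position, family_id, strand, circular`` (one row per gene);
GFF3 is accepted read-only for single genomes.  Distance matrices are
exchanged in the Phylip square dialect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", "?")

__all__ = [
    "GeneRecord",
    "Genome",
    "GenomeSet",
    "DistanceMatrix",
    "read_gene_orders",
    "write_gene_orders",
    "read_gff3_orders",
    "filter_genomes",
    "read_phylip_matrix",
    "write_phylip_matrix",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene: an ortholog-family token plus a strand (+, - or ? for unknown)."""

    family_id: str
    strand: str = "?"

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be a non-empty string")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class Genome:
    """An identified, ordered sequence of genes, circular unless flagged otherwise."""

    genome_id: str
    genes: tuple[GeneRecord, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if len(self.genes) < 1:
            raise ValueError(f"genome {self.genome_id!r} has no genes")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def families(self) -> frozenset[str]:
        return frozenset(g.family_id for g in self.genes)

    @classmethod
    def from_families(
        cls,
        genome_id: str,
        families: Iterable[str],
        strands: Iterable[str] | None = None,
        circular: bool = True,
    ) -> "Genome":
        """Build a genome from family tokens (strand ? unless given)."""
        fams = list(families)
        strs = list(strands) if strands is not None else ["?"] * len(fams)
        if len(strs) != len(fams):
            raise ValueError("strands and families must have equal length")
        return cls(genome_id, tuple(GeneRecord(f, s) for f, s in zip(fams, strs)), circular)


class GenomeSet(Mapping[str, Genome]):
    """A collection of genomes keyed by id, sharing one family vocabulary."""

    def __init__(self, genomes: Iterable[Genome]):
        self._genomes: dict[str, Genome] = {}
        for g in genomes:
            if g.genome_id in self._genomes:
                raise ValueError(f"duplicate genome_id {g.genome_id!r}")
            self._genomes[g.genome_id] = g

    def __getitem__(self, key: str) -> Genome:
        return self._genomes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._genomes)

    def __len__(self) -> int:
        return len(self._genomes)

    @property
    def ids(self) -> list[str]:
        return list(self._genomes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeSet):
            return NotImplemented
        return self._genomes == other._genomes


class DistanceMatrix:
    """Symmetric pairwise distance table with a zero diagonal.

    Entries from the synteny-index, gene-content and directed-pairs
    distances all lie in [0, 1]; the container only enforces symmetry,
    non-negativity and the zero diagonal so that transformed matrices
    remain representable.
    """

    #: symmetry slack beyond which construction is refused
    ASYM_TOL = 1e-9

    def __init__(self, taxa: Iterable[str], values: np.ndarray):
        self.taxa = list(taxa)
        values = np.asarray(values, dtype=float)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("taxon ids must be unique")
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} taxa")
        if np.isnan(values).any():
            raise ValueError("distance matrix contains NaN")
        if (values < 0).any():
            raise ValueError("distances must be non-negative")
        if np.abs(values - values.T).max(initial=0.0) > self.ASYM_TOL:
            raise ValueError("matrix is not symmetric")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.values = values

    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


_REQUIRED_COLUMNS = ("genome_id", "position", "family_id")


def read_gene_orders(path) -> GenomeSet:
    """Read a gene-order TSV into a :class:`GenomeSet`.

    Columns ``genome_id``, ``position`` and ``family_id`` are required;
    ``strand`` (defaults to unknown) and ``circular`` (defaults to true,
    the prokaryotic norm) are optional.  Genes are ordered by ascending
    position; only the rank order is semantic, so gaps in the position
    column are re-densified with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gene-order TSV is missing required column {col!r}")
    if "strand" not in df.columns:
        df["strand"] = "?"
    if "circular" not in df.columns:
        df["circular"] = "true"
    df["position"] = df["position"].astype(int)

    dups = df.duplicated(subset=["genome_id", "position"])
    if dups.any():
        bad = df.loc[dups, ["genome_id", "position"]].iloc[0]
        raise ValueError(
            f"duplicate (genome_id, position) entry: ({bad['genome_id']!r}, {bad['position']})"
        )

    genomes = []
    for gid, grp in df.groupby("genome_id", sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(len(pos))):
            warnings.warn(
                f"genome {gid!r}: positions are not 0..n-1; re-densifying by rank order",
                stacklevel=2,
            )
        circ_vals = set(grp["circular"].str.lower())
        if len(circ_vals) > 1:
            raise ValueError(f"genome {gid!r}: inconsistent circular flags")
        circular = circ_vals.pop() in ("true", "1", "yes", "t")
        strands = [s if s in ("+", "-") else "?" for s in grp["strand"]]
        genomes.append(
            Genome(
                str(gid),
                tuple(GeneRecord(f, s) for f, s in zip(grp["family_id"], strands)),
                circular,
            )
        )
    return GenomeSet(genomes)


def write_gene_orders(gs: GenomeSet, path) -> None:
    """Write a GenomeSet to the native gene-order TSV (inverse of read_gene_orders)."""
    rows = []
    for gid in gs.ids:
        g = gs[gid]
        for i, rec in enumerate(g.genes):
            rows.append((gid, i, rec.family_id, rec.strand, str(g.circular).lower()))
    pd.DataFrame(
        rows, columns=["genome_id", "position", "family_id", "strand", "circular"]
    ).to_csv(path, sep="\t", index=False)


def read_gff3_orders(path, family_attribute: str, genome_id: str | None = None,
                     circular: bool = True) -> Genome:
    """Extract a gene order from a GFF3 file.

    CDS features (or gene features when no CDS are present) are sorted by
    start coordinate; the ortholog-family token is taken from the attribute
    named ``family_attribute``.  Features lacking the attribute are skipped
    and the skip count is reported as a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = list(db.features_of_type("CDS"))
    if not feats:
        feats = list(db.features_of_type("gene"))
    if not feats:
        raise ValueError(f"no CDS or gene features in {path}")
    feats.sort(key=lambda f: (f.seqid, f.start, f.end))

    records, skipped = [], 0
    for f in feats:
        fam = f.attributes.get(family_attribute)
        if not fam:
            skipped += 1
            continue
        strand = f.strand if f.strand in ("+", "-") else "?"
        records.append(GeneRecord(fam[0], strand))
    if skipped:
        warnings.warn(
            f"{skipped} feature(s) lacked attribute {family_attribute!r} and were skipped",
            stacklevel=2,
        )
    if not records:
        raise ValueError(f"no feature carried attribute {family_attribute!r}")
    gid = genome_id or str(path)
    return Genome(gid, tuple(records), circular)


def filter_genomes(gs: GenomeSet, min_genes: int = 500) -> GenomeSet:
    """Drop genomes with fewer than ``min_genes`` genes.

    Sparse annotations (few assigned gene families) carry essentially no
    synteny signal and behave as noise in the distance matrix, so they are
    excluded before reconstruction; the default cut-off is 500 genes.
    Removed ids and sizes are logged.  Fewer than 4 surviving genomes is a
    hard error because neighbor joining needs at least 4 taxa.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    kept, removed = [], []
    for gid in gs.ids:
        (kept if len(gs[gid]) >= min_genes else removed).append(gid)
    for gid in removed:
        logger.info("filter_genomes: removed %s (%d genes < %d)", gid, len(gs[gid]), min_genes)
    if len(kept) < 4:
        raise ValueError(
            f"only {len(kept)} genomes remain after filtering at {min_genes} genes; "
            "neighbor joining needs at least 4 taxa"
        )
    return GenomeSet(gs[gid] for gid in kept)


def write_phylip_matrix(D: DistanceMatrix, path, relaxed: bool = False) -> None:
    """Write a distance matrix in the Phylip square dialect.

    Strict mode pads names to 10 characters (and refuses longer ones);
    ``relaxed`` emits full names followed by whitespace.
    """
    lines = [f"    {len(D)}"]
    for name, row in zip(D.taxa, D.values):
        if relaxed:
            label = f"{name}  "
        else:
            if len(name) > 10:
                raise ValueError(
                    f"taxon name {name!r} exceeds 10 characters; use relaxed=True"
                )
            label = f"{name:<10}"
        lines.append(label + " ".join(f"{v:.6f}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_phylip_matrix(path) -> DistanceMatrix:
    """Read a Phylip square distance matrix (strict or relaxed names)."""
    with open(path) as fh:
        tokens_lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    n = int(tokens_lines[0].split()[0])
    if len(tokens_lines) != n + 1:
        raise ValueError(f"expected {n} matrix rows, found {len(tokens_lines) - 1}")
    taxa, rows = [], []
    for ln in tokens_lines[1:]:
        parts = ln.split()
        taxa.append(parts[0])
        row = [float(x) for x in parts[1:]]
        if len(row) != n:
            raise ValueError(f"row for {parts[0]!r} has {len(row)} values, expected {n}")
        rows.append(row)
    return DistanceMatrix(taxa, np.array(rows))
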