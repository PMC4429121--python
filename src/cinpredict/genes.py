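"""Gene annotations, gene-pair Hi-C scores, and chromatin interaction networks.

A chromatin interaction network (CIN) is an unweighted, undirected graph per
chromosome per resolution. Nodes are genes (or bins, for the bin-based
variant); an edge connects two nodes whose normalized Hi-C score strictly
exceeds a genome-wide percentile threshold. Gene-pair scores are assigned
from the bin-level matrix either by MAX-mapping (maximum over all spanned bin
pairs) or TSS-mapping (the bin pair holding the two transcription start
sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .contact import NormalizedContactMatrix

__all__ = [
    "GeneAnnotation",
    "GenePairScoreMatrix",
    "CIN",
    "read_genes_bed",
    "write_genes_bed",
    "bins_of_gene",
    "tss_bin",
    "map_genes",
    "genome_threshold",
    "build_cin",
    "build_bin_cin",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (0-based half-open) with strand-derived TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end`` on - strand."""
        return self.start if self.strand == "+" else self.end


def read_genes_bed(path) -> list[GeneAnnotation]:
    """Read BED6 annotations (chrom, start, end, name, score, strand)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            genes.append(GeneAnnotation(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return genes


def write_genes_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def bins_of_gene(g: GeneAnnotation, bin_size: int, n_bins: int | None = None):
    """All bins overlapping [start, end) under half-open arithmetic."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    first = g.start // bin_size
    last = (g.end - 1) // bin_size
    if n_bins is not None and last >= n_bins:
        raise ValueError(f"gene {g.gene_id} extends beyond the contact matrix")
    return set(range(first, last + 1))


def tss_bin(g: GeneAnnotation, bin_size: int) -> int:
    """Bin containing the TSS base (end-1 for minus-strand genes)."""
    pos = g.tss if g.strand == "+" else g.tss - 1
    return pos // bin_size


@dataclass
class GenePairScoreMatrix:
    """Normalized Hi-C score per intra-chromosomal gene pair.

    ``scores`` is gene x gene, symmetric; NaN marks excluded pairs (the
    diagonal and pairs whose mapping collapses to a single bin, whose Hi-C
    value would be a self-contact artifact).
    """

    chrom: str
    resolution: int
    mapping: str
    gene_ids: list[str]
    scores: np.ndarray


def map_genes(
    n: NormalizedContactMatrix, genes: list[GeneAnnotation], mapping: str
) -> GenePairScoreMatrix:
    """Assign gene-pair scores from the bin matrix by MAX- or TSS-mapping.

    Diagonal cells of the bin matrix (self-contacts) never contribute; a
    gene pair with no off-diagonal bin pair (both genes confined to the same
    single bin) is excluded (NaN), as is any TSS pair sharing a bin.
    """
    if any(g.chrom != n.chrom for g in genes):
        raise ValueError("all genes must lie on the matrix chromosome")
    ng = len(genes)
    out = np.full((ng, ng), np.nan)
    if mapping == "MAX":
        c = n.scores.astype(float).copy()
        np.fill_diagonal(c, -np.inf)
        # reduce rows then columns over each gene's bin range (bins are
        # contiguous, so slices suffice)
        spans = [sorted(bins_of_gene(g, n.bin_size, n.n_bins)) for g in genes]
        row_red = np.stack([c[s[0] : s[-1] + 1].max(axis=0) for s in spans])
        for b, sb in enumerate(spans):
            out[:, b] = row_red[:, sb[0] : sb[-1] + 1].max(axis=1)
        out[~np.isfinite(out)] = np.nan
    elif mapping == "TSS":
        tb = np.array([tss_bin(g, n.bin_size) for g in genes])
        if tb.max() >= n.n_bins or tb.min() < 0:
            raise ValueError("TSS outside contact matrix")
        out = n.scores[np.ix_(tb, tb)].astype(float).copy()
        out[tb[:, None] == tb[None, :]] = np.nan
    else:
        raise ValueError("mapping must be 'MAX' or 'TSS'")
    np.fill_diagonal(out, np.nan)
    return GenePairScoreMatrix(n.chrom, n.bin_size, mapping, [g.gene_id for g in genes], out)


def genome_threshold(score_matrices, percentile: float) -> float:
    """Empirical quantile of pooled upper-triangle scores across chromosomes.

    Linear interpolation between order statistics; NaN (excluded) pairs are
    ignored.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    pools = []
    for s in score_matrices:
        arr = s.scores if hasattr(s, "scores") else np.asarray(s)
        iu = np.triu_indices(arr.shape[0], 1)
        v = arr[iu]
        pools.append(v[~np.isnan(v)])
    pool = np.concatenate(pools)
    if pool.size == 0:
        raise ValueError("empty score pool")
    return float(np.quantile(pool, percentile))


@dataclass
class CIN:
    """Unweighted, undirected chromatin interaction network.

    ``adjacency`` has a(x, y) in {0, 1}, zero diagonal. Isolated nodes are
    retained.
    """

    chrom: str
    resolution: int
    mapping: str
    nodes: list
    adjacency: np.ndarray
    node_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a.astype(np.int8)
        self.node_index = {nid: i for i, nid in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degree)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency, 1))))
        return g

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for i, j in zip(*np.nonzero(np.triu(self.adjacency, 1))):
                fh.write(f"{self.nodes[i]}\t{self.nodes[j]}\n")


def build_cin(s: GenePairScoreMatrix, threshold: float) -> CIN:
    """Edge (x, y) iff the gene-pair score strictly exceeds ``threshold``."""
    with np.errstate(invalid="ignore"):
        a = (s.scores > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return CIN(s.chrom, s.resolution, s.mapping, list(s.gene_ids), a)


def build_bin_cin(n: NormalizedContactMatrix, threshold: float) -> CIN:
    """Bin-based CIN: nodes are bins, edges are supra-threshold contacts."""
    a = (n.scores > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return CIN(n.chrom, n.bin_size, "BIN", list(range(n.n_bins)), a)
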