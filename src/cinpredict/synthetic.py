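"""Synthetic genomes, contact matrices, and spatial expression matrices.

The generator plants the statistical structure the analysis assumes, so that
the full pipeline runs and is validated without any external download:

* contacts follow a power-law genomic-distance decay, modulated by
  contiguous compartment blocks (boosted within-block contacts, emulating
  chromatin domains) that alternate between two compartment types (boosted
  long-range same-type contacts, emulating A/B-compartment-style or
  transcription-factory-style interactions); counts are Poisson;
* expression gives genes of the same block (and, more weakly, the same
  compartment type) shared latent per-sample factors, so that same-block
  gene pairs have elevated Spearman co-expression — the planted link between
  3-D contact structure and spatial co-expression that the classifier is
  asked to recover.

Setting ``signal=0`` severs that link (expression becomes pure noise), and
``block_boost=1, type_boost=1`` flattens the contact structure to pure decay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import ContactMatrix, read_contact_matrix, write_contact_matrix
from .coexpression import read_expression, write_expression
from .genes import GeneAnnotation, read_genes_bed, write_genes_bed

__all__ = [
    "SyntheticConfig",
    "Bundle",
    "generate_genome",
    "generate_contacts",
    "generate_expression",
    "generate_dataset",
    "default_configs",
    "load_dataset",
    "gene_block",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic chromosome.

    Defaults emulate the scale of the real per-chromosome networks (a few
    hundred genes) at 40 kb base bins: a 30 Mb chromosome with 300 genes,
    15 compartment blocks of ~2 Mb alternating between 2 types, power-law
    contact decay with exponent 1, within-block contacts boosted 5x and
    long-range same-type contacts 2x, and 200 expression samples in which a
    0.7 share of each gene's profile comes from its block/type factors.
    """

    chrom: str = "chr1"
    n_genes: int = 300
    chrom_length: int = 30_000_000
    base_bin: int = 40_000
    decay_alpha: float = 1.0
    n_blocks: int = 15
    block_boost: float = 5.0
    type_boost: float = 2.0
    contact_depth: float = 100.0
    expr_samples: int = 200
    signal: float = 0.7
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.signal <= 1:
            raise ValueError("signal must lie in [0, 1]")
        for name in ("n_genes", "chrom_length", "base_bin", "n_blocks",
                     "expr_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.chrom_length / self.base_bin)


def _block_of_bin(cfg: SyntheticConfig, bins: np.ndarray) -> np.ndarray:
    """Contiguous equal-run block id per bin; type alternates with block."""
    return np.minimum(bins * cfg.n_blocks // cfg.n_bins, cfg.n_blocks - 1)


def gene_block(cfg: SyntheticConfig, g: GeneAnnotation) -> int:
    """Compartment block of a gene, via its midpoint bin."""
    mid_bin = ((g.start + g.end) // 2) // cfg.base_bin
    return int(_block_of_bin(cfg, np.array([mid_bin]))[0])


def generate_genome(cfg: SyntheticConfig) -> list[GeneAnnotation]:
    """Non-overlapping genes, lengths log-normal around 30 kb, random strand.

    Free space between genes is distributed as random gaps; genes are sorted
    by position and deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = rng.lognormal(mean=np.log(30_000), sigma=0.5, size=cfg.n_genes)
    lengths = np.maximum(lengths.astype(int), 200)
    free = cfg.chrom_length - int(lengths.sum())
    if free < 0:
        raise ValueError("infeasible packing: genes do not fit on the chromosome")
    gaps = rng.dirichlet(np.ones(cfg.n_genes + 1)) * free
    gaps = gaps.astype(int)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes, pos = [], 0
    for i in range(cfg.n_genes):
        pos += gaps[i]
        genes.append(
            GeneAnnotation(
                f"{cfg.chrom}_g{i:04d}", cfg.chrom, pos, pos + int(lengths[i]),
                str(strands[i]),
            )
        )
        pos += int(lengths[i])
    assert genes[-1].end <= cfg.chrom_length
    return genes


def generate_contacts(cfg: SyntheticConfig, genes=None) -> ContactMatrix:
    """Poisson contact counts with distance decay and compartment structure.

    E[c_ij] = depth * (1+|i-j|)^(-alpha) * block_boost^[same block]
                                         * type_boost^[same type, diff block]
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_bins
    bins = np.arange(n)
    block = _block_of_bin(cfg, bins)
    btype = block % 2
    dist = np.abs(bins[:, None] - bins[None, :])
    e = cfg.contact_depth * (1.0 + dist) ** (-cfg.decay_alpha)
    same_block = block[:, None] == block[None, :]
    same_type = (btype[:, None] == btype[None, :]) & ~same_block
    e = e * np.where(same_block, cfg.block_boost, 1.0)
    e = e * np.where(same_type, cfg.type_boost, 1.0)
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(e[iu])
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(cfg.chrom, cfg.base_bin, counts)


def generate_expression(cfg: SyntheticConfig, genes: list[GeneAnnotation]) -> pd.DataFrame:
    """Samples x genes expression with shared block/type latent factors.

    x_gv = signal * (f_block(g),v + 0.5 * f_type(g),v)
           + (1 - signal) * eps_gv,  eps ~ N(0, noise_sd)
    """
    rng = np.random.default_rng(cfg.seed + 2)
    nv = cfg.expr_samples
    f_block = rng.standard_normal((cfg.n_blocks, nv))
    f_type = rng.standard_normal((2, nv))
    blocks = np.array([gene_block(cfg, g) for g in genes])
    shared = f_block[blocks] + 0.5 * f_type[blocks % 2]
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(genes), nv))
    x = cfg.signal * shared + (1.0 - cfg.signal) * noise
    return pd.DataFrame(
        x.T,
        index=[f"v{v:04d}" for v in range(nv)],
        columns=[g.gene_id for g in genes],
    )


@dataclass
class Bundle:
    """A multi-chromosome synthetic dataset."""

    configs: list[SyntheticConfig]
    contacts: dict[str, ContactMatrix]
    genes: dict[str, list[GeneAnnotation]]
    expression: pd.DataFrame  # samples x all genes

    @property
    def chroms(self) -> list[str]:
        return [c.chrom for c in self.configs]

    @property
    def genes_by_chrom(self) -> dict[str, list[str]]:
        return {c: [g.gene_id for g in gs] for c, gs in self.genes.items()}


def default_configs(seed: int = 0) -> list[SyntheticConfig]:
    """The default two-chromosome study conditions (~300 and ~200 genes)."""
    return [
        SyntheticConfig(chrom="chr1", seed=seed),
        SyntheticConfig(
            chrom="chr2", n_genes=200, chrom_length=20_000_000, n_blocks=10,
            seed=seed + 1,
        ),
    ]


def generate_dataset(cfgs: list[SyntheticConfig], out_dir=None) -> Bundle:
    """Generate a bundle; optionally write all artifact input formats.

    Written files (triplet contacts, BED6 genes, expression TSV, JSON
    manifest) round-trip through the package readers.
    """
    if not cfgs:
        raise ValueError("need at least one chromosome config")
    if len({c.chrom for c in cfgs}) != len(cfgs):
        raise ValueError("chromosome names must be unique")
    contacts, genes, exprs = {}, {}, []
    for cfg in cfgs:
        gs = generate_genome(cfg)
        genes[cfg.chrom] = gs
        contacts[cfg.chrom] = generate_contacts(cfg, gs)
        exprs.append(generate_expression(cfg, gs))
    expression = pd.concat(exprs, axis=1)
    bundle = Bundle(list(cfgs), contacts, genes, expression)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cfg in cfgs:
            write_contact_matrix(contacts[cfg.chrom], out / f"{cfg.chrom}.contacts.tsv")
            write_genes_bed(genes[cfg.chrom], out / f"{cfg.chrom}.genes.bed")
        write_expression(expression, out / "expression.tsv")
        manifest = {"chromosomes": [asdict(c) for c in cfgs]}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def load_dataset(in_dir) -> Bundle:
    """Re-load a written bundle via the package readers."""
    out = Path(in_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    cfgs = [SyntheticConfig(**c) for c in manifest["chromosomes"]]
    contacts, genes = {}, {}
    for cfg in cfgs:
        contacts[cfg.chrom] = read_contact_matrix(
            out / f"{cfg.chrom}.contacts.tsv", "triplet", cfg.chrom, cfg.base_bin,
            n_bins=cfg.n_bins,
        )
        genes[cfg.chrom] = read_genes_bed(out / f"{cfg.chrom}.genes.bed")
    expression = read_expression(out / "expression.tsv")
    return Bundle(cfgs, contacts, genes, expression)
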