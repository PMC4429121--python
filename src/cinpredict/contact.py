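"""Binned intra-chromosomal Hi-C contact matrices: I/O, coarsening, normalization.

Raw Hi-C contact counts carry a strong genomic-distance bias: bins that are
close along the linear genome interact frequently regardless of 3D folding.
Two normalizations are provided. The rank-based method replaces each contact
by its relative rank among contacts at a similar genomic distance, with the
per-distance pools extended to a fixed length ``L`` so that normalized scores
are comparable across chromosomes. The average-based method divides each
contact by the mean contact at the same distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "NormalizedContactMatrix",
    "read_contact_matrix",
    "write_contact_matrix",
    "coarsen",
    "rank_normalize",
    "average_normalize",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome at one bin size."""

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be nonnegative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class NormalizedContactMatrix:
    """Distance-normalized contact scores; ``method`` is 'rank' or 'average'."""

    chrom: str
    bin_size: int
    scores: np.ndarray
    method: str
    L: int | None = field(default=None)

    @property
    def n_bins(self) -> int:
        return self.scores.shape[0]


def read_contact_matrix(
    path,
    format: str = "triplet",
    chrom: str = "chr",
    bin_size: int = 40_000,
    n_bins: int | None = None,
) -> ContactMatrix:
    """Read a contact matrix from whitespace-delimited text.

    ``triplet`` rows are ``i j count`` with 0-based bin indices; missing cells
    are zero and the matrix is mirrored. ``dense`` is a square whitespace
    matrix and must already be symmetric.
    """
    if format == "triplet":
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            if n_bins is None:
                raise ValueError("n_bins required for an empty triplet file")
            return ContactMatrix(chrom, bin_size, np.zeros((n_bins, n_bins)))
        i = data[:, 0].astype(int)
        j = data[:, 1].astype(int)
        c = data[:, 2]
        if np.any(c < 0):
            raise ValueError("negative contact count in triplet file")
        n = int(max(i.max(), j.max())) + 1 if n_bins is None else n_bins
        if i.max() >= n or j.max() >= n:
            raise ValueError("bin index out of declared range")
        m = np.zeros((n, n))
        np.add.at(m, (i, j), c)
        upper, lowT = np.triu(m, 1), np.tril(m, -1).T
        both = (upper != 0) & (lowT != 0)
        if np.any(both & ~np.isclose(upper, lowT)):
            raise ValueError("conflicting values for mirrored triplet cells")
        merged = np.where(upper != 0, upper, lowT)
        m = np.diag(np.diag(m)) + merged + merged.T
        return ContactMatrix(chrom, bin_size, m)
    if format == "dense":
        m = np.loadtxt(path, ndmin=2)
        return ContactMatrix(chrom, bin_size, m)
    raise ValueError(f"unknown format {format!r}")


def write_contact_matrix(m: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as ``i j count`` triplets."""
    iu, ju = np.triu_indices(m.n_bins)
    c = m.counts[iu, ju]
    keep = c != 0
    np.savetxt(path, np.column_stack([iu[keep], ju[keep], c[keep]]), fmt="%d\t%d\t%g")


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum consecutive bins into larger ones; a trailing partial block is kept.

    Total matrix mass is conserved exactly.
    """
    if int(factor) != factor or factor <= 0:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return ContactMatrix(m.chrom, m.bin_size, m.counts.copy())
    edges = np.arange(0, m.n_bins, factor)
    out = np.add.reduceat(np.add.reduceat(m.counts, edges, axis=0), edges, axis=1)
    return ContactMatrix(m.chrom, m.bin_size * factor, out)


def _superdiag_pool(counts: np.ndarray, m_idx: int, L: int):
    """Build the distance pool for super-diagonal ``m_idx``.

    Starts with the super-diagonal's own values, then extends toward length
    ``L`` with equal element counts drawn from the neighboring
    super-diagonals below and above ``m`` (nearest distance first, each
    diagonal in increasing bin-index order). Keeping the extension balanced
    around distance m leaves the normalized score free of any residual
    distance trend; where one side cannot supply its half (m near the main
    diagonal or the matrix corner) the pool stays short and the caller
    rescales ranks to [1, L]. Deterministic.
    """
    n = counts.shape[0]
    own = np.diagonal(counts, m_idx)
    need = L - own.size
    if need <= 0:
        return own, own.size
    half = (need + 1) // 2

    def side(direction: int) -> np.ndarray:
        vals, step = [], 1
        got = 0
        while got < half:
            k = m_idx + direction * step
            if not 1 <= k <= n - 1:
                break
            d = np.diagonal(counts, k)
            vals.append(d)
            got += d.size
            step += 1
        return np.concatenate(vals) if vals else np.empty(0)

    lower, upper = side(-1), side(+1)
    t = min(half, lower.size, upper.size)
    pool = np.concatenate([own, lower[:t], upper[:t]])
    return pool[:L], own.size


def rank_normalize(m: ContactMatrix, L: int) -> NormalizedContactMatrix:
    """Replace each contact by its average rank within its distance pool.

    Every off-diagonal score lies in [1, L]; ties get the average rank. Each
    distance pool is extended symmetrically from neighboring super-diagonals
    (see ``_superdiag_pool``); whenever a pool cannot reach length ``L`` —
    boundary distances, or a matrix with fewer than L off-diagonal entries —
    ranks are linearly rescaled to span [1, L] so that scores remain
    comparable across distances and chromosomes. The main diagonal is
    assigned no rank (set to 0) and is excluded downstream.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    n = m.n_bins
    if n == 0:
        raise ValueError("empty matrix")
    scores = np.zeros((n, n))
    for k in range(1, n):
        pool, n_own = _superdiag_pool(m.counts, k, L)
        ranks = rankdata(pool)[:n_own]
        if pool.size != L and pool.size > 1:
            ranks = 1.0 + (ranks - 1.0) * (L - 1.0) / (pool.size - 1.0)
        elif pool.size == 1:
            ranks = np.full(1, (1.0 + L) / 2.0)
        log.debug("chrom %s distance %d: pool size %d", m.chrom, k, pool.size)
        idx = np.arange(n - k)
        scores[idx, idx + k] = ranks
        scores[idx + k, idx] = ranks
    return NormalizedContactMatrix(m.chrom, m.bin_size, scores, "rank", L)


def average_normalize(m: ContactMatrix) -> NormalizedContactMatrix:
    """Divide each contact by the mean contact at its genomic distance.

    Distance classes with zero mean yield 0.
    """
    n = m.n_bins
    scores = np.zeros((n, n))
    for k in range(n):
        d = np.diagonal(m.counts, k)
        mu = d.mean() if d.size else 0.0
        vals = d / mu if mu > 0 else np.zeros_like(d)
        idx = np.arange(n - k)
        scores[idx, idx + k] = vals
        scores[idx + k, idx] = vals
    return NormalizedContactMatrix(m.chrom, m.bin_size, scores, "average")
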