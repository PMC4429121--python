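"""Standard and scale-aware topological measures of a CIN; feature assembly.

Scale-aware topological measures (STMs) evaluate graph-topological notions on
the diffusion kernel

    K^beta = exp(beta * (A - D)),

the matrix exponential of the scaled negative graph Laplacian (A adjacency,
D degree matrix). K^beta is symmetric, doubly stochastic, and nonnegative;
beta sets the topological scale, from near-identity (local structure, small
beta) to component-uniform smoothing (compartment-level structure, large
beta). Five measures are computed in both a standard and a scale-aware
version:

  shortest path   s(x,y)          s_beta(x,y)  = -log K(x,y)
  Jaccard index   J(x,y)          J_beta(x,y)  = sum_i min(K_xi, K_iy) / sum_i max(K_xi, K_iy)
  centrality      c(x) (closeness; degree optional)
                                  c_beta(x)    = 1 - K(x,x)
  betweenness     b(x)            b_beta(z)    = 1/N^2 sum_{x,y} (s_b(x,y) - s_b(x,z) - s_b(z,y))
  clustering      cc(x)           cc_beta(x)   = sum_{i != x} K(x,i) J_beta(x,i)

Node measures are converted to link measures by the absolute difference and
the mean over the two endpoint genes, giving eight link features per measure
set: [s, J, |dc|, mean c, |db|, mean b, |dcc|, mean cc].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

from .genes import CIN

__all__ = [
    "DiffusionKernel",
    "NodeMeasures",
    "beta_schedule",
    "diffusion_kernel",
    "diffusion_kernels",
    "standard_measures",
    "scale_aware_measures",
    "link_features",
    "assemble_features",
    "direct_link_features",
]

#: kernel entries below this are treated as zero when taking -log
KERNEL_EPS = 1e-12


@dataclass
class DiffusionKernel:
    beta: float
    K: np.ndarray


@dataclass
class NodeMeasures:
    """Per-node measures plus the link-level shortest-path and Jaccard
    matrices they accompany."""

    centrality: np.ndarray  # closeness (or degree) / c_beta
    betweenness: np.ndarray
    clustering: np.ndarray
    s: np.ndarray  # pairwise shortest-path matrix / s_beta
    jaccard: np.ndarray  # pairwise Jaccard matrix / J_beta
    degree: np.ndarray | None = None


def beta_schedule(n_steps: int = 10, beta_min: float = 0.0001, beta_max: float = 10.0):
    """Geometric-like diffusion-scale schedule.

    beta = (2^(6b) - 1) / (2^6 - 1) * (beta_max - beta_min) + beta_min with b
    stepping uniformly from 0 to 1 in ``n_steps`` values; the defaults give
    [0.0001, 0.09, 0.24, 0.47, 0.8, 1.4, 2.3, 3.8, 6.2, 10] at one-to-two
    decimal precision.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    b = np.linspace(0.0, 1.0, n_steps)
    return (2 ** (6 * b) - 1) / (2**6 - 1) * (beta_max - beta_min) + beta_min


def _laplacian_eig(cin: CIN):
    lap = cin.adjacency.astype(float) - np.diag(cin.degree.astype(float))
    w, v = np.linalg.eigh(lap)
    return w, v


def _kernel_from_eig(w, v, beta: float) -> np.ndarray:
    k = (v * np.exp(beta * w)) @ v.T
    k = (k + k.T) / 2.0  # kill round-off asymmetry
    np.clip(k, 0.0, None, out=k)
    return k


def diffusion_kernel(cin: CIN, beta: float) -> DiffusionKernel:
    """K^beta = exp(beta (A - D)) via symmetric eigendecomposition."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    w, v = _laplacian_eig(cin)
    return DiffusionKernel(beta, _kernel_from_eig(w, v, beta))


def diffusion_kernels(cin: CIN, betas) -> list[DiffusionKernel]:
    """Kernels for several scales sharing one eigendecomposition."""
    w, v = _laplacian_eig(cin)
    return [DiffusionKernel(float(b), _kernel_from_eig(w, v, b)) for b in betas]


def standard_measures(cin: CIN, unreachable_cap: float | None = None) -> NodeMeasures:
    """Standard (fixed-scale) topological measures.

    Shortest paths are counted in edges; unreachable pairs are capped at the
    node count N (a finite value exceeding any realizable distance), and
    closeness uses the same cap. Isolated nodes get closeness 0. Jaccard uses
    open neighborhoods; betweenness counts all geodesics with endpoints
    excluded; clustering is the standard open-neighborhood definition.
    """
    n = cin.n_nodes
    cap = float(n) if unreachable_cap is None else unreachable_cap
    deg = cin.degree.astype(float)
    if n == 0:
        z = np.zeros(0)
        return NodeMeasures(z, z, z, np.zeros((0, 0)), np.zeros((0, 0)), z)
    s = shortest_path(csr_matrix(cin.adjacency), method="D", unweighted=True)
    s[np.isinf(s)] = cap
    farness = s.sum(axis=1)
    with np.errstate(divide="ignore"):
        closeness = np.where((deg > 0) & (farness > 0), 1.0 / farness, 0.0)
    a = cin.adjacency.astype(float)
    common = a @ a
    union = deg[:, None] + deg[None, :] - common
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, common / union, 0.0)
    np.fill_diagonal(jac, np.where(deg > 0, 1.0, 0.0))
    g = cin.to_networkx()
    btw = np.array([v for _, v in sorted(nx.betweenness_centrality(g, normalized=False).items())])
    cc = np.array([v for _, v in sorted(nx.clustering(g).items())])
    return NodeMeasures(closeness, btw, cc, s, jac, deg)


def scale_aware_measures(k: DiffusionKernel) -> NodeMeasures:
    """Scale-aware measures from a diffusion kernel, exactly per the formulas.

    Sums run over all nodes. Kernel entries below ``KERNEL_EPS`` are clipped
    before the log, capping s_beta at -log(eps) for node pairs in distinct
    components. b_beta may be negative; no sign correction is applied.
    """
    K = k.K
    n = K.shape[0]
    S = -np.log(np.clip(K, KERNEL_EPS, None))
    c = 1.0 - np.diag(K)
    row = K.sum(axis=1)
    d1 = cdist(K, K, metric="cityblock")
    num = row[:, None] + row[None, :] - d1
    den = row[:, None] + row[None, :] + d1
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(den > 0, num / den, 0.0)
    srow = S.sum(axis=1)
    btw = (S.sum() - 2.0 * n * srow) / n**2
    cc = (K * jac).sum(axis=1) - np.diag(K) * np.diag(jac)
    return NodeMeasures(c, btw, cc, S, jac)


_FEATURE_ORDER = ("s", "J", "dC", "mC", "dB", "mB", "dCC", "mCC")


def link_features(m: NodeMeasures, pairs: np.ndarray) -> np.ndarray:
    """Eight link features per gene pair.

    ``pairs`` is an (n_pairs, 2) array of node indices. Defined for every
    pair of nodes in the CIN, edge or not.
    """
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size and pairs.max() >= m.s.shape[0]:
        raise KeyError("pair references a node absent from the CIN")
    x, y = pairs[:, 0], pairs[:, 1]
    cols = [
        m.s[x, y],
        m.jaccard[x, y],
        np.abs(m.centrality[x] - m.centrality[y]),
        (m.centrality[x] + m.centrality[y]) / 2.0,
        np.abs(m.betweenness[x] - m.betweenness[y]),
        (m.betweenness[x] + m.betweenness[y]) / 2.0,
        np.abs(m.clustering[x] - m.clustering[y]),
        (m.clustering[x] + m.clustering[y]) / 2.0,
    ]
    return np.column_stack(cols)


def _pair_indices(cin: CIN, pairs) -> np.ndarray:
    try:
        return np.array([[cin.node_index[a], cin.node_index[b]] for a, b in pairs])
    except KeyError as e:
        raise KeyError(f"pair references node {e} absent from the CIN") from None


def assemble_features(
    cins: list[CIN],
    pairs,
    betas=None,
    mode: str = "stm",
    centrality: str = "closeness",
) -> pd.DataFrame:
    """Column-wise concatenation of 8-feature blocks over CINs (and scales).

    Column names follow ``<measure>|<scale|std>|<resolution>|<mapping>``.
    ``mode`` is 'standard', 'stm', or 'both'. With 10 CINs (5 resolutions x
    2 mappings) and 10 scales in STM mode this yields the full 800-column
    table; one CIN in standard mode yields 8 columns.
    """
    if mode not in ("standard", "stm", "both"):
        raise ValueError("mode must be 'standard', 'stm', or 'both'")
    pairs = list(pairs)
    blocks, names = [], []
    for cin in cins:
        idx = _pair_indices(cin, pairs)
        tag = f"{cin.resolution}|{cin.mapping}"
        if mode in ("standard", "both"):
            m = standard_measures(cin)
            if centrality == "degree":
                m.centrality = m.degree
            blocks.append(link_features(m, idx))
            names += [f"{f}|std|{tag}" for f in _FEATURE_ORDER]
        if mode in ("stm", "both"):
            if betas is None:
                betas = beta_schedule()
            for kern in diffusion_kernels(cin, betas):
                blocks.append(link_features(scale_aware_measures(kern), idx))
                names += [f"{f}|b={kern.beta:.4g}|{tag}" for f in _FEATURE_ORDER]
    index = pd.MultiIndex.from_tuples(pairs, names=["gene_a", "gene_b"])
    return pd.DataFrame(np.hstack(blocks), index=index, columns=names)


def direct_link_features(cin: CIN, pairs) -> pd.DataFrame:
    """Single binary feature: presence of the direct CIN edge a(x, y)."""
    idx = _pair_indices(cin, list(pairs))
    vals = cin.adjacency[idx[:, 0], idx[:, 1]].astype(float)
    index = pd.MultiIndex.from_tuples(list(pairs), names=["gene_a", "gene_b"])
    return pd.DataFrame({f"link|std|{cin.resolution}|{cin.mapping}": vals}, index=index)
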