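"""Enrichment and association statistics, and 2-D embedding of feature tables.

The co-localization test asks whether strongly co-expressed gene pairs have
higher normalized Hi-C scores than pairs without strong co-expression, via a
one-tailed Wilcoxon rank-sum (Mann-Whitney) test; Bonferroni correction over
the chromosome x resolution grid is applied by the scan helper.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GenePairScoreMatrix

__all__ = [
    "colocalization_test",
    "enrichment_scan",
    "matrix_correlation",
    "embed_2d",
]


def _paired_scores(scores: GenePairScoreMatrix, labels: pd.DataFrame):
    idx = {g: i for i, g in enumerate(scores.gene_ids)}
    vals, cls = [], []
    mat = scores.scores
    for a, b, lab in labels[["gene_a", "gene_b", "label"]].itertuples(index=False):
        if lab == "excluded" or a not in idx or b not in idx:
            continue
        v = mat[idx[a], idx[b]]
        if np.isnan(v):  # pair has no Hi-C score at this resolution
            continue
        vals.append(v)
        cls.append(lab)
    vals = np.asarray(vals)
    cls = np.asarray(cls)
    return vals[cls == "strong"], vals[cls == "none"]


def colocalization_test(scores: GenePairScoreMatrix, labels: pd.DataFrame):
    """One-tailed Wilcoxon rank-sum: strong pairs score higher than none.

    Returns (W statistic, one-tailed p, -log10 p). Exact enumeration of the
    rank-sum distribution is used when both groups have at most 20 tie-free
    values; the tie-corrected, continuity-corrected normal approximation
    otherwise.
    """
    strong, none_ = _paired_scores(scores, labels)
    if strong.size == 0 or none_.size == 0:
        raise ValueError("both label classes must be non-empty")
    pooled = np.concatenate([strong, none_])
    small = max(strong.size, none_.size) <= 20
    method = "exact" if small and np.unique(pooled).size == pooled.size else "asymptotic"
    res = stats.mannwhitneyu(strong, none_, alternative="greater", method=method)
    p = float(res.pvalue)
    return float(res.statistic), p, float(-np.log10(max(p, 1e-300)))


def enrichment_scan(
    score_matrices: dict[tuple[str, int], GenePairScoreMatrix],
    labels_by_chrom: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Co-localization test over a (chrom, resolution) grid with Bonferroni.

    The Bonferroni family size is the number of tests actually run. Returns
    the enrichment report: chrom, resolution, mapping, group sizes, W, p,
    -log10 p, and the significance flag.
    """
    rows = []
    for (chrom, res), scores in score_matrices.items():
        labels = labels_by_chrom[chrom]
        strong, none_ = _paired_scores(scores, labels)
        w, p, nlp = colocalization_test(scores, labels)
        rows.append(
            dict(
                chrom=chrom,
                resolution=res,
                mapping=scores.mapping,
                n_strong=strong.size,
                n_none=none_.size,
                W=w,
                p=p,
                minus_log10_p=nlp,
            )
        )
    report = pd.DataFrame(rows)
    n_tests = len(report)
    report["significant_after_bonferroni"] = report["p"] < alpha / n_tests
    report.attrs["n_tests"] = n_tests
    report.attrs["alpha"] = alpha
    return report


def matrix_correlation(hic: GenePairScoreMatrix, rho: pd.DataFrame) -> float:
    """Pearson r between Hi-C and co-expression over matched gene pairs.

    Vectorizes the upper triangles over the shared gene universe, dropping
    pairs without a Hi-C score. Symmetric in its arguments.
    """
    shared = [g for g in hic.gene_ids if g in rho.columns]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes")
    hidx = {g: i for i, g in enumerate(hic.gene_ids)}
    hsub = hic.scores[np.ix_([hidx[g] for g in shared], [hidx[g] for g in shared])]
    rsub = rho.loc[shared, shared].to_numpy()
    iu = np.triu_indices(len(shared), 1)
    h, r = hsub[iu], rsub[iu]
    keep = ~np.isnan(h) & ~np.isnan(r)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 scored pairs in common")
    return float(stats.pearsonr(h[keep], r[keep]).statistic)


def embed_2d(
    X: pd.DataFrame, perplexity: float = 30.0, init_dims: int = 50, seed: int = 0
) -> np.ndarray:
    """t-SNE map of a feature table: one 2-D point per gene pair.

    Dimensionality is first reduced to ``init_dims`` principal components
    (capped at the table shape); constant feature columns are dropped with a
    warning. Seeded and deterministic.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    X = pd.DataFrame(X)
    arr = X.to_numpy(dtype=float)
    keep = arr.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)")
        arr = arr[:, keep]
    n, d = arr.shape
    k = min(init_dims, d, n)
    if k < d:
        arr = PCA(n_components=k, random_state=seed).fit_transform(arr)
    perplexity = min(perplexity, (n - 1) / 3)
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return ts.fit_transform(arr)
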