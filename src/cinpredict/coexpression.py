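"""Spatial co-expression: Spearman correlation of expression profiles and
percentile-based gene-pair labels.

Two genes are "strongly co-expressed" (class ``strong``) when the Spearman
correlation of their spatial expression profiles exceeds the 90th percentile
of all intra-chromosomal correlations pooled across chromosomes, and "without
strong co-expression" (class ``none``) when it falls below the pooled median;
pairs in between are ``excluded`` from training. Spearman correlation makes
the labels invariant to any strictly monotone transform of the expression
values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_expression",
    "write_expression",
    "spearman_coexpression",
    "label_pairs",
    "labels_to_frame",
]


def read_expression(path) -> pd.DataFrame:
    """Read a samples x genes TSV whose first column is the sample id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="sample")


def spearman_coexpression(
    expr: pd.DataFrame, genes_by_chrom: dict[str, list[str]]
) -> dict[str, pd.DataFrame]:
    """Spearman rho for every intra-chromosomal gene pair.

    Returns one symmetric gene x gene DataFrame per chromosome. Constant
    expression columns (Spearman undefined) are dropped with a warning.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    out = {}
    for chrom, gene_ids in genes_by_chrom.items():
        cols = [g for g in gene_ids if g in expr.columns]
        sub = expr[cols]
        const = sub.columns[(sub.nunique() <= 1).values]
        if len(const):
            warnings.warn(
                f"{chrom}: dropping {len(const)} constant expression column(s): "
                f"{list(const)[:5]}"
            )
            sub = sub.drop(columns=const)
        k = sub.shape[1]
        if k < 2:
            rho = np.ones((k, k))
        else:
            rho = np.atleast_2d(stats.spearmanr(sub.to_numpy(), axis=0).statistic)
            if rho.shape != (k, k):  # scipy returns a scalar for 2 columns
                r = float(rho.ravel()[0])
                rho = np.array([[1.0, r], [r, 1.0]])
        out[chrom] = pd.DataFrame(rho, index=sub.columns, columns=sub.columns)
    return out


def label_pairs(
    rho_by_chrom: dict[str, pd.DataFrame],
    pos_pct: float = 0.9,
    neg_pct: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Three-way gene-pair labels from pooled genome-wide percentiles.

    ``strong`` iff rho > the pooled ``pos_pct`` quantile; ``none`` iff rho <
    the pooled ``neg_pct`` quantile; everything else (boundaries included) is
    ``excluded``. With pos_pct == neg_pct no pair is excluded.
    """
    if pos_pct < neg_pct:
        raise ValueError("pos_pct must be >= neg_pct")
    pools = []
    for rho in rho_by_chrom.values():
        iu = np.triu_indices(rho.shape[0], 1)
        pools.append(rho.to_numpy()[iu])
    pool = np.concatenate(pools)
    t_pos = float(np.quantile(pool, pos_pct))
    t_neg = float(np.quantile(pool, neg_pct))
    out = {}
    for chrom, rho in rho_by_chrom.items():
        ids = list(rho.columns)
        iu, ju = np.triu_indices(len(ids), 1)
        r = rho.to_numpy()[iu, ju]
        cls = np.where(r > t_pos, "strong", np.where(r < t_neg, "none", "excluded"))
        out[chrom] = pd.DataFrame(
            {
                "gene_a": [ids[i] for i in iu],
                "gene_b": [ids[j] for j in ju],
                "rho": r,
                "label": cls,
            }
        )
    return out


def labels_to_frame(labels: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-chromosome label tables with a chromosome column."""
    return pd.concat(
        [df.assign(chrom=chrom) for chrom, df in labels.items()], ignore_index=True
    )
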