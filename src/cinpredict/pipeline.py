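"""End-to-end orchestration: data -> networks -> features -> evaluation.

The experiment menu mirrors the study's feature modes:

  direct_link        presence/absence of the direct CIN edge (1 column)
  std_single         standard measures, one resolution, one mapping (8)
  std_multi          standard measures over the resolution grid (8 x R)
  std_multi_tssmax   standard, resolutions x both mappings (8 x R x 2)
  stm_single         scale-aware measures, one resolution (8 x 10 scales)
  stm_multi          STMs over the resolution grid, one mapping (8 x 10 x R)
  stm_multi_tssmax   STMs, resolutions x both mappings (800 at R=5)
  bin_cin            standard + STMs of the bin-based CIN, gene pairs
                     addressed through their TSS bins

Within each resolution the raw counts are coarsened, rank-normalized with a
pool length of twice the bin count of the largest chromosome at that
resolution, mapped to gene pairs, and thresholded at the genome-wide 90th
percentile to build one CIN per chromosome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, evaluation, prediction, synthetic, topology
from .contact import average_normalize, coarsen, rank_normalize
from .genes import (
    CIN,
    GenePairScoreMatrix,
    build_bin_cin,
    build_cin,
    genome_threshold,
    map_genes,
    tss_bin,
)

log = logging.getLogger(__name__)

__all__ = ["NetworkSet", "build_networks", "mode_features", "run_experiment", "MODES"]

MODES = (
    "direct_link",
    "std_single",
    "std_multi",
    "std_multi_tssmax",
    "stm_single",
    "stm_multi",
    "stm_multi_tssmax",
    "bin_cin",
)

DEFAULT_RESOLUTION_FACTORS = (1, 2, 3, 4, 5)  # 40..200 kb at a 40 kb base


@dataclass
class NetworkSet:
    """Normalized matrices, gene-pair scores, thresholds and CINs for a
    resolution x mapping grid."""

    resolutions: list[int]
    mappings: list[str]
    norms: dict = field(default_factory=dict)  # (res, chrom) -> NormalizedContactMatrix
    scores: dict = field(default_factory=dict)  # (res, mapping, chrom) -> GenePairScoreMatrix
    thresholds: dict = field(default_factory=dict)  # (res, mapping) -> float
    cins: dict = field(default_factory=dict)  # (res, mapping, chrom) -> CIN
    bin_cins: dict = field(default_factory=dict)  # (res, chrom) -> CIN


def build_networks(
    bundle: synthetic.Bundle,
    resolutions=None,
    mappings=("MAX", "TSS"),
    percentile: float = 0.9,
    normalization: str = "rank",
    L: int | None = None,
    with_bin_cin: bool = False,
) -> NetworkSet:
    """Normalize, map and threshold contact data into per-chromosome CINs.

    ``resolutions`` are bin sizes in bp (multiples of the base bin). The rank
    pool length defaults to twice the bin count of the largest chromosome at
    each resolution; a fixed ``L`` overrides that at every resolution.
    """
    base = bundle.configs[0].base_bin
    if resolutions is None:
        resolutions = [base * f for f in DEFAULT_RESOLUTION_FACTORS]
    ns = NetworkSet(list(resolutions), list(mappings))
    for res in resolutions:
        factor = res // base
        coarse = {c: coarsen(m, factor) for c, m in bundle.contacts.items()}
        l_res = L if L is not None else 2 * max(m.n_bins for m in coarse.values())
        for chrom, m in coarse.items():
            if normalization == "rank":
                ns.norms[(res, chrom)] = rank_normalize(m, l_res)
            elif normalization == "average":
                ns.norms[(res, chrom)] = average_normalize(m)
            else:
                raise ValueError("normalization must be 'rank' or 'average'")
        for mapping in mappings:
            mats = {
                chrom: map_genes(ns.norms[(res, chrom)], bundle.genes[chrom], mapping)
                for chrom in bundle.chroms
            }
            thr = genome_threshold(list(mats.values()), percentile)
            ns.thresholds[(res, mapping)] = thr
            for chrom, s in mats.items():
                ns.scores[(res, mapping, chrom)] = s
                ns.cins[(res, mapping, chrom)] = build_cin(s, thr)
        if with_bin_cin:
            pool = [ns.norms[(res, c)].scores for c in bundle.chroms]
            thr = genome_threshold(pool, percentile)
            for chrom in bundle.chroms:
                ns.bin_cins[(res, chrom)] = build_bin_cin(ns.norms[(res, chrom)], thr)
    return ns


def _mode_plan(mode: str, resolutions: list[int], single_res: int | None):
    single = single_res or resolutions[0]
    if mode == "direct_link":
        return [single], ["MAX"], None
    if mode == "std_single":
        return [single], ["MAX"], "standard"
    if mode == "std_multi":
        return resolutions, ["MAX"], "standard"
    if mode == "std_multi_tssmax":
        return resolutions, ["MAX", "TSS"], "standard"
    if mode == "stm_single":
        return [single], ["MAX"], "stm"
    if mode == "stm_multi":
        return resolutions, ["MAX"], "stm"
    if mode == "stm_multi_tssmax":
        return resolutions, ["MAX", "TSS"], "stm"
    if mode == "bin_cin":
        return [resolutions[-1]], ["BIN"], "both"
    raise ValueError(f"unknown feature mode {mode!r}; choose one of {MODES}")


def mode_features(
    bundle: synthetic.Bundle,
    networks: NetworkSet,
    labels_by_chrom: dict[str, pd.DataFrame],
    mode: str,
    betas=None,
    single_res: int | None = None,
    centrality: str = "closeness",
) -> dict[str, tuple[pd.DataFrame, np.ndarray]]:
    """Feature table and binary labels per chromosome for one feature mode.

    Rows are the strong/none labeled gene pairs of each chromosome (excluded
    pairs are dropped).
    """
    res_list, mappings, feat_mode = _mode_plan(mode, networks.resolutions, single_res)
    betas = topology.beta_schedule() if betas is None else betas
    out = {}
    for chrom in bundle.chroms:
        lab = labels_by_chrom[chrom]
        lab = lab[lab["label"] != "excluded"]
        pairs = list(zip(lab["gene_a"], lab["gene_b"]))
        y = lab["label"].to_numpy()
        if mode == "direct_link":
            cin = networks.cins[(res_list[0], "MAX", chrom)]
            X = topology.direct_link_features(cin, pairs)
        elif mode == "bin_cin":
            res = res_list[0]
            cin = networks.bin_cins[(res, chrom)]
            gmap = {g.gene_id: tss_bin(g, res) for g in bundle.genes[chrom]}
            bin_pairs = [(gmap[a], gmap[b]) for a, b in pairs]
            X = topology.assemble_features(
                [cin], bin_pairs, betas=betas, mode="both", centrality=centrality
            )
            X.index = pd.MultiIndex.from_tuples(pairs, names=["gene_a", "gene_b"])
        else:
            cins = [
                networks.cins[(res, mapping, chrom)]
                for res in res_list
                for mapping in mappings
            ]
            X = topology.assemble_features(
                cins, pairs, betas=betas, mode=feat_mode, centrality=centrality
            )
        out[chrom] = (X, y)
    return out


def _load_bundle(cfg: dict, seed: int) -> synthetic.Bundle:
    if "data_dir" in cfg:
        return synthetic.load_dataset(cfg["data_dir"])
    overrides = cfg.get("synthetic", {})
    if isinstance(overrides, list):
        cfgs = [synthetic.SyntheticConfig(**o) for o in overrides]
    else:
        cfgs = synthetic.default_configs(seed)
        if overrides:
            cfgs = [synthetic.replace(c, **overrides) for c in cfgs]
    return synthetic.generate_dataset(cfgs)


def run_experiment(config: dict | str | Path, out_dir=None) -> dict:
    """Run a configured experiment end to end; return (and optionally write)
    the report.

    Config keys (all optional except where noted): ``seed``; ``synthetic``
    (per-chromosome overrides) or ``data_dir``; ``mode`` (feature mode, see
    ``MODES``); ``resolutions`` (bp list); ``single_res``; ``percentile``;
    ``normalization``; ``pos_pct``/``neg_pct``; ``classifier`` (hidden_nodes,
    ridge); ``folds``; ``tasks`` (subset of cv, enrich, select, loco, embed).
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    mode = config.get("mode", "stm_multi_tssmax")
    tasks = config.get("tasks", ["cv", "enrich"])
    bundle = _load_bundle(config, seed)
    networks = build_networks(
        bundle,
        resolutions=config.get("resolutions"),
        percentile=config.get("percentile", 0.9),
        normalization=config.get("normalization", "rank"),
        L=config.get("L"),
        with_bin_cin=(mode == "bin_cin"),
    )
    rho = coexpression.spearman_coexpression(bundle.expression, bundle.genes_by_chrom)
    labels = coexpression.label_pairs(
        rho, config.get("pos_pct", 0.9), config.get("neg_pct", 0.5)
    )
    report: dict = {"seed": seed, "mode": mode, "resolutions": networks.resolutions}
    feats = mode_features(
        bundle, networks, labels, mode, single_res=config.get("single_res")
    )
    report["feature_columns"] = {
        c: list(map(str, X.columns)) for c, (X, _) in feats.items()
    }
    spec = prediction.ClassifierSpec(
        hidden_nodes=config.get("classifier", {}).get("hidden_nodes", 800),
        ridge=config.get("classifier", {}).get("ridge", 1e-3),
        seed=seed,
    )
    if "cv" in tasks:
        folds = config.get("folds", 10)
        cv_out = {}
        for chrom, (X, y) in feats.items():
            cv = prediction.cross_validate(spec, X.to_numpy(), y, folds, seed)
            cv_out[chrom] = {
                "per_fold_auc": cv.fold_aucs,
                "mean_auc": cv.mean_auc,
                "median_auc": cv.median_auc,
                "folds": folds,
                "n_pairs": len(y),
            }
            log.info("CV %s mode=%s mean AUC %.3f", chrom, mode, cv.mean_auc)
        cv_out["median_over_chroms"] = float(
            np.median([v["mean_auc"] for v in cv_out.values()])
        )
        report["cv"] = cv_out
    if "enrich" in tasks:
        grid = {
            (chrom, res): networks.scores[(res, "MAX", chrom)]
            for res in networks.resolutions
            for chrom in bundle.chroms
        }
        enr = evaluation.enrichment_scan(grid, labels)
        report["enrichment"] = enr.to_dict(orient="records")
        report["enrichment_n_tests"] = int(enr.attrs["n_tests"])
    if "select" in tasks:
        sel_spec = prediction.ClassifierSpec(hidden_nodes=100, ridge=spec.ridge, seed=seed)
        sel_out = {}
        for chrom, (X, y) in feats.items():
            sel = prediction.forward_select(sel_spec, X, y, folds=5, seed=seed)
            sel_out[chrom] = {
                "per_fold_selected": [list(map(str, s)) for s in sel.per_fold_selected],
                "union": list(map(str, sel.union)),
                "per_fold_auc": sel.per_fold_auc,
                "mean_auc": sel.mean_auc,
            }
        report["selection"] = sel_out
    if "loco" in tasks and len(bundle.chroms) > 1:
        X_by = {c: X for c, (X, _) in feats.items()}
        y_by = {c: y for c, (_, y) in feats.items()}
        report["loco"] = prediction.leave_one_chromosome_out(spec, X_by, y_by)
    if "embed" in tasks:
        emb = {}
        for chrom, (X, _) in feats.items():
            coords = evaluation.embed_2d(X, seed=seed)
            emb[chrom] = coords.tolist()
        report["embedding"] = emb
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        if "enrich" in tasks:
            pd.DataFrame(report["enrichment"]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
    return report
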