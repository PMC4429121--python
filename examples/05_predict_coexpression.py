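"""Predict co-expression from CIN topology and compare feature modes.

A random-projection network (one hidden layer, ridge-solved output) is
cross-validated on (a) the single direct-link indicator and (b) scale-aware
topological measures from multi-resolution CINs. The AUC gap shows how much
indirect, multi-scale interaction structure adds over direct contacts.
"""

from cinpredict import coexpression, pipeline, prediction, synthetic

cfgs = [
    synthetic.SyntheticConfig(chrom="chr1", n_genes=60, chrom_length=6_000_000,
                              n_blocks=4, seed=1),
    synthetic.SyntheticConfig(chrom="chr2", n_genes=50, chrom_length=5_000_000,
                              n_blocks=4, seed=2),
]
bundle = synthetic.generate_dataset(cfgs)
networks = pipeline.build_networks(bundle)
rho = coexpression.spearman_coexpression(bundle.expression, bundle.genes_by_chrom)
labels = coexpression.label_pairs(rho)

spec = prediction.ClassifierSpec(hidden_nodes=800, seed=1)
for mode in ("direct_link", "stm_multi_tssmax"):
    feats = pipeline.mode_features(bundle, networks, labels, mode)
    for chrom, (X, y) in feats.items():
        cv = prediction.cross_validate(spec, X.to_numpy(), y, folds=5, seed=1)
        print(f"{mode:>18} {chrom}: {X.shape[1]:3d} features, "
              f"mean AUC {cv.mean_auc:.3f}")
print("AUC 0.5 is chance, 1.0 perfect: topology across scales and")
print("resolutions predicts co-expression far better than direct links.")
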