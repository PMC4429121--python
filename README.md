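# cinpredict

Predict spatial gene co-expression from the topology of multi-resolution
**chromatin interaction networks (CINs)**.

## The problem

Hi-C measures how often pairs of genomic bins touch in the 3-D folded
genome. Direct contact between two genes is a poor predictor of whether
they are co-expressed: most co-expressed gene pairs are *not* in direct
contact, but are connected indirectly — through shared neighbors, chromatin
loops, or whole compartments. `cinpredict` implements an analysis pipeline
that captures those indirect relationships and uses them to predict, for
every intra-chromosomal gene pair, whether the two genes are strongly
co-expressed across a spatial expression atlas.

The package is aimed at regulatory-genomics researchers who want to relate
3-D genome organization to expression. Because the original cortex Hi-C and
spatial in-situ expression data are large external downloads, the package
ships a first-class synthetic-data generator that plants the same
statistical structure (distance-decaying, compartment-structured contacts;
block-wise co-expression), so every stage runs and is validated offline.

## The method

1. **Rank-based normalization.** Each Hi-C contact c_ij is replaced by its
   rank within a pool of contacts at similar genomic distance
   (super-diagonals of the contact matrix, extended symmetrically to a
   fixed length L = twice the bin count of the largest chromosome), giving
   scores ĉ_ij ∈ [1, L] that are free of the distance-decay bias and
   comparable across chromosomes. An average-based normalization
   (c_ij / mean at distance) is provided for comparison.
2. **Multi-resolution CINs.** Matrices are coarsened to bin sizes
   40–200 kb, mapped to gene pairs by MAX-mapping
   (ĥ_xy = max_{i∈x, j∈y} ĉ_ij) or TSS-mapping (the TSS bin pair), and
   thresholded at the genome-wide 90th percentile: one unweighted graph per
   chromosome per resolution, genes as nodes.
3. **Scale-aware topological measures (STMs).** Five measures — shortest
   path, Jaccard index, closeness/degree centrality, betweenness,
   clustering coefficient — are computed both in standard form and on the
   diffusion kernel **K^β = e^{β(A−D)}** at ten scales
   β ∈ [0.0001, 10] (e.g. s^β(x,y) = −log K^β_{x,y},
   c^β(x) = 1 − K^β_{x,x}). Node measures become link features via the
   mean and absolute difference over the pair, giving 8 features per
   measure set and up to 800 features per pair (8 × 10 scales × 5
   resolutions × 2 mappings).
4. **Labels and classifier.** Gene pairs are labeled *strong* (Spearman
   co-expression above the genome-wide 90th percentile) or *none* (below
   the median). A random-projection network (one hidden layer of 800 seeded
   random units, sigmoid activation, ridge-solved output layer) is
   evaluated by stratified 10-fold cross-validated AUC, with forward
   feature selection and leave-one-chromosome-out transfer as companions.
5. **Enrichment.** A one-tailed Wilcoxon rank-sum test per chromosome and
   resolution asks whether strongly co-expressed pairs have higher
   normalized Hi-C scores (Bonferroni-corrected over the grid).

## Worked example

`examples/05_predict_coexpression.py` simulates two small chromosomes
(60 and 50 genes), builds CINs at 40–200 kb, labels pairs by co-expression
and cross-validates two feature modes:

```
       direct_link chr1:   1 features, mean AUC 0.549
       direct_link chr2:   1 features, mean AUC 0.538
  stm_multi_tssmax chr1: 800 features, mean AUC 0.962
  stm_multi_tssmax chr2: 800 features, mean AUC 0.977
```

The direct-link indicator is barely better than chance (AUC 0.5), while the
800 scale-aware multi-resolution features recover the planted
structure–expression link almost perfectly — the qualitative ordering the
method is designed to demonstrate. The other example scripts walk through
simulation (`01`), normalization and CIN construction (`02`), kernels and
feature blocks (`03`), and the co-localization enrichment test (`04`).

A thin CLI wraps the same pipeline:

```sh
cinpredict simulate --seed 0 --out-dir data/
cinpredict train --data-dir data/ --mode stm_multi_tssmax --seed 0
cinpredict run --config experiment.yaml --out-dir results/
```

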