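"""Rank-normalize a contact matrix and build the chromatin interaction
network (CIN) at two resolutions.

Rank normalization replaces each contact by its rank among contacts at a
similar genomic distance (pools of fixed length L), removing the distance
decay; the CIN keeps an edge wherever a gene pair's normalized score exceeds
the genome-wide 90th percentile.
"""

import numpy as np

from cinpredict import contact, genes, synthetic

cfg = synthetic.SyntheticConfig(chrom="chr1", n_genes=60, chrom_length=6_000_000,
                                n_blocks=4, seed=1)
gene_list = synthetic.generate_genome(cfg)
raw = synthetic.generate_contacts(cfg)

for factor in (1, 5):
    coarse = contact.coarsen(raw, factor)
    norm = contact.rank_normalize(coarse, L=2 * coarse.n_bins)
    scores = genes.map_genes(norm, gene_list, "MAX")
    thr = genes.genome_threshold([scores], 0.9)
    cin = genes.build_cin(scores, thr)
    mean_near = np.nanmean(np.diagonal(norm.scores, 1))
    print(f"{coarse.bin_size // 1000:>3} kb bins: 90th-pct threshold {thr:7.1f}, "
          f"CIN {cin.n_nodes} nodes / {cin.n_edges} edges, "
          f"mean rank at distance 1 = {mean_near:.0f} (unbiased ~ {coarse.n_bins + 0.5:.0f})")

print("after normalization the mean rank is flat in distance, so edges mark")
print("contacts that are strong FOR THEIR distance, not merely nearby bins.")
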