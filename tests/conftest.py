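import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles module

from cinpredict import coexpression, pipeline, prediction, synthetic

#: seed for every session-scoped run of the default study conditions
SEED = 1


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    """Symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture(scope="session")
def default_bundle():
    """The default two-chromosome synthetic dataset (the study conditions)."""
    return synthetic.generate_dataset(synthetic.default_configs(SEED))


@pytest.fixture(scope="session")
def default_networks(default_bundle):
    return pipeline.build_networks(default_bundle)


@pytest.fixture(scope="session")
def default_labels(default_bundle):
    rho = coexpression.spearman_coexpression(
        default_bundle.expression, default_bundle.genes_by_chrom
    )
    return coexpression.label_pairs(rho)


@pytest.fixture(scope="session")
def stm_features(default_bundle, default_networks, default_labels):
    """Full 800-column STM multi-resolution TSS+MAX feature tables."""
    return pipeline.mode_features(
        default_bundle, default_networks, default_labels, "stm_multi_tssmax"
    )


@pytest.fixture(scope="session")
def stm_cv(stm_features):
    """10-fold CV of the 800-hidden-node classifier on the STM features."""
    spec = prediction.ClassifierSpec(seed=SEED)
    return {
        chrom: prediction.cross_validate(spec, X.to_numpy(), y, 10, SEED)
        for chrom, (X, y) in stm_features.items()
    }


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small fast bundle for structural (non-statistical) checks."""
    cfgs = [
        synthetic.SyntheticConfig(
            chrom="chrA", n_genes=40, chrom_length=4_000_000, n_blocks=4, seed=11
        ),
        synthetic.SyntheticConfig(
            chrom="chrB", n_genes=30, chrom_length=3_000_000, n_blocks=3, seed=12
        ),
    ]
    return synthetic.generate_dataset(cfgs)
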