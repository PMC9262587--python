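import numpy as np
import pandas as pd
import pytest

import hybridloh as h


@pytest.fixture(scope="session")
def mini_config():
    """Three scaled-down chromosomes, 1 kb marker spacing, no rDNA locus."""
    return h.HybridGenomeConfig.miniature(n_chroms=3, scale=0.5, seed=7)


@pytest.fixture(scope="session")
def mini_genome(mini_config):
    return h.build_hybrid_genome(mini_config)


@pytest.fixture(scope="session")
def full_config():
    return h.HybridGenomeConfig(seed=11)


@pytest.fixture(scope="session")
def full_genome(full_config):
    return h.build_hybrid_genome(full_config)


def uniform_counts(genome, depth=30):
    """Noise-free count table at exactly ``depth`` reads per site."""
    snps = genome.snps
    n = len(snps)
    return pd.DataFrame({
        "chrom": snps["chrom"],
        "pos": snps["pos"],
        "allele_W": snps["allele_W"],
        "allele_Y": snps["allele_Y"],
        "count_W": np.full(n, depth // 2, dtype=np.int64),
        "count_Y": np.full(n, depth - depth // 2, dtype=np.int64),
    })
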