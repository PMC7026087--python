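import numpy as np
import pytest

import stressnet as sn


@pytest.fixture
def small_counts():
    """8 genes x 6 samples with known totals 0,1,2,...,7 per gene."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(8)]
    counts = np.zeros((8, 6), dtype=int)
    for i in range(8):
        # distribute total i over 6 samples
        for _ in range(i):
            counts[i, rng.integers(6)] += 1
    samples = [f"s{j}" for j in range(6)]
    return sn.CountMatrix(genes, counts, samples)


@pytest.fixture
def factorial_design():
    cfg = sn.SimConfig(n_genes=50, n_per_cell=2, seed=0)
    return cfg, sn.generate_design(cfg)


@pytest.fixture
def null_dataset():
    """Small fully-null dataset: 300 genes, 2 genotypes, 1 region."""
    cfg = sn.SimConfig(n_genes=300, n_per_cell=6, genotypes=("XX_F", "XY_M"),
                       regions=("BLA",), seed=42)
    design = sn.generate_design(cfg)
    counts, truth = sn.simulate_counts(cfg, design)
    return cfg, design, counts, truth


def make_expression(n_genes=40, n_samples=12, seed=0, gene_prefix="g"):
    """Plain Gaussian expression matrix for unit tests."""
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    return sn.ExpressionMatrix(genes, rng.standard_normal((n_genes, n_samples)),
                               samples)
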