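import numpy as np
import pytest

from gilnet.expression_io import ExpressionMatrix
from gilnet.network_build import CoexpressionNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    values = rng.normal(size=(10, 5))
    return ExpressionMatrix(
        [f"G{i}" for i in range(10)], [f"S{j}" for j in range(5)], values
    )


@pytest.fixture
def triangle_network():
    return CoexpressionNetwork(
        [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.85)]
    )


def planted_block_expression(
    seed,
    n_noise=400,
    n_blocks=5,
    block_size=20,
    loading=3.0,
    noise_sd=1.0,
    n_samples=50,
):
    """Latent-factor matrix with independent planted blocks, then noise rows.

    Genes 0..n_blocks*block_size-1 form consecutive blocks with an exact
    within-block correlation loading^2 / (loading^2 + noise_sd^2).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_noise + n_blocks * block_size
    values = rng.normal(0.0, noise_sd, (n_genes, n_samples))
    for k in range(n_blocks):
        z = rng.normal(0.0, 1.0, n_samples)
        values[k * block_size:(k + 1) * block_size] += loading * z
    values += rng.normal(0.0, 1.0, n_genes)[:, None]
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{j:03d}" for j in range(n_samples)]
    block_of = {
        gene_ids[i]: (i // block_size if i < n_blocks * block_size else -1)
        for i in range(n_genes)
    }
    return ExpressionMatrix(gene_ids, sample_ids, values), block_of


def planted_pairs(block_of):
    """Canonical within-block gene pairs."""
    from collections import defaultdict

    groups = defaultdict(list)
    for g, b in block_of.items():
        if b >= 0:
            groups[b].append(g)
    pairs = set()
    for genes in groups.values():
        genes = sorted(genes)
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                pairs.add((a, b))
    return pairs
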