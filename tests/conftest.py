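import numpy as np
import pytest

from degatlas.simulate import simulate_compendium, simulate_counts, simulate_genesets


@pytest.fixture(scope="session")
def small_compendium():
    """A 12-comparison, 2-block synthetic compendium with a planted query."""
    return simulate_compendium(
        n_comparisons=12, n_blocks=2, n_genes=1500, seed=11
    )


@pytest.fixture(scope="session")
def small_counts():
    """A 300-gene, 2x5-sample counts experiment with 10% planted DE."""
    return simulate_counts(n_genes=300, n_per_group=5, de_fraction=0.1, seed=5)


@pytest.fixture(scope="session")
def geneset_db():
    rng = np.random.default_rng(3)
    universe = [f"G{i:05d}" for i in range(1500)]
    return simulate_genesets(
        n_sets=40, size_range=(15, 120), universe=universe, seed=3
    )
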