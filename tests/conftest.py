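import numpy as np
import pandas as pd
import pytest

from triohet import CountMatrix, TrioSimConfig, generate_trio_counts


@pytest.fixture
def small_counts() -> CountMatrix:
    """Deterministic 50-gene x 6-sample count matrix with varied lengths."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j}" for j in range(6)]
    counts = pd.DataFrame(rng.integers(0, 500, size=(50, 6)), index=genes, columns=samples)
    lengths = pd.Series(rng.integers(200, 5000, size=50), index=genes)
    return CountMatrix(counts=counts, lengths=lengths)


@pytest.fixture
def trio_dataset():
    """Small simulated trio with planted SDG structure, shared across tests."""
    cfg = TrioSimConfig(
        n_genes=400, seed=7, dispersion=0.05,
        n_sdg_parent_shared=15, n_sdg_hybrid_specific=15,
    )
    return generate_trio_counts(cfg)
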