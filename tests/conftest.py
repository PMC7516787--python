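import numpy as np
import pandas as pd
import pytest

from mblasso.data_model import GenotypeMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genotypes():
    """4 x 3 panel covering all three genotype codes."""
    X = np.array([
        [1, 0, -1],
        [0, 1, -1],
        [-1, 0, 1],
        [0, -1, 1],
    ])
    snp_map = pd.DataFrame({
        "snp_id": ["s1", "s2", "s3"],
        "chromosome": [1, 1, 2],
        "position": [100, 2000, 100],
    })
    return GenotypeMatrix(X, snp_map)


@pytest.fixture
def small_panel(rng):
    """199 x 300 HWE panel with one strong and one weak causal SNP."""
    from mblasso import simulator as sim

    G = sim.simulate_genotypes(199, 300, qtn_indices=[50, 150], seed=7)
    b = sim.effects_from_heritability([0.3, 0.05], [0.3, 0.3], sigma2_e=10.0)
    y = (10.0 + G.X[:, 50] * b[0] + G.X[:, 150] * b[1]
         + rng.normal(0, np.sqrt(10.0), 199))
    return G, PhenotypeVector(y), np.array([50, 150]), b
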