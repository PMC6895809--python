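import numpy as np
import pandas as pd
import pytest

from eiphkit.genio import MAP_COLUMNS, GenotypeMatrix
from eiphkit.simulate import SimConfig, simulate_cohort


def make_matrix(calls, chromosomes=None, positions=None, sexes=None):
    """Small GenotypeMatrix from a raw call array."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    snp_map = pd.DataFrame({
        "snp_id": [f"S{j}" for j in range(m)],
        "chromosome": chromosomes if chromosomes is not None else [1] * m,
        "position": positions if positions is not None else [1000 * (j + 1) for j in range(m)],
        "allele_a": ["A"] * m,
        "allele_b": ["G"] * m,
    })[MAP_COLUMNS]
    return GenotypeMatrix(calls=calls, individuals=[f"I{i}" for i in range(n)],
                          snp_map=snp_map, sexes=sexes)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale synthetic cohort shared across tests (72 horses, 3,000 SNPs)."""
    return simulate_cohort(SimConfig(n_snps=3000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
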