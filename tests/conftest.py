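import numpy as np
import pandas as pd
import pytest

from pgxeqtl.core import GenotypeMatrix
from pgxeqtl.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One shared small simulated study (fast, deterministic)."""
    return simulate_study(SimulationConfig(seed=7, n_snps=300, n_genes=80))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_gm(dosages: np.ndarray, chrom: str = "chr1", pos0: int = 1000,
            spacing: int = 100) -> GenotypeMatrix:
    """GenotypeMatrix from a samples x snps array with synthetic metadata."""
    n, m = dosages.shape
    snp_ids = [f"rs{j:04d}" for j in range(m)]
    samples = [f"S{i:02d}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [pos0 + j * spacing for j in range(m)],
            "ref_allele": "A",
            "alt_allele": "G",
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=samples, columns=snp_ids),
        snps=snps,
    )
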