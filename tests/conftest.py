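import numpy as np
import pandas as pd
import pytest

from swinegp.containers import GenotypeMatrix
from swinegp.simdata import SimConfig, simulate_genotypes, simulate_phenotypes


def make_geno(dosages: np.ndarray, chrom: str = "1") -> GenotypeMatrix:
    """Wrap a raw dosage array in a GenotypeMatrix with stub metadata."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "snp_id": [f"s{j}" for j in range(m)],
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=d, snp_meta=meta, sample_ids=[f"i{i}" for i in range(n)])


@pytest.fixture(scope="session")
def herd():
    """A mid-sized simulated herd with one trait, shared across tests."""
    cfg = SimConfig(n_individuals=250, n_snps=400, n_qtl=25, h2=0.5, seed=42)
    geno = simulate_genotypes(cfg)
    table, truth = simulate_phenotypes(geno, cfg)
    return cfg, geno, table, truth


@pytest.fixture(scope="session")
def small_xy():
    """Plain regression features/target for ML tests."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((150, 20))
    y = 2.0 * X[:, 0] + np.sin(2.0 * X[:, 1]) + 0.3 * rng.standard_normal(150)
    return X, y
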