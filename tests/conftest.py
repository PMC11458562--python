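import numpy as np
import pytest

from neuroscca.datatypes import GenotypeMatrix, SnpRecord
from neuroscca.simulate import SimulationConfig, simulate_cohort


def make_genotypes(dosages, ids=None, chrom="1", info_r2=None) -> GenotypeMatrix:
    """Small hand-built GenotypeMatrix for unit tests."""
    D = np.asarray(dosages, dtype=float)
    n, p = D.shape
    ids = ids or [f"snp{j}" for j in range(p)]
    info_r2 = info_r2 or {}
    snps = [SnpRecord(id=ids[j], chrom=chrom, pos=1000 * (j + 1), a1="A", a2="G",
                      info_r2=info_r2.get(ids[j])) for j in range(p)]
    return GenotypeMatrix(sample_ids=[f"s{i}" for i in range(n)], snps=snps, dosages=D)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared mid-size synthetic cohort with planted structure."""
    cfg = SimulationConfig(n_samples=400, n_snps=80, seed=11)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
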