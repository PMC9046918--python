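import numpy as np
import pandas as pd
import pytest

from charrqg import synthdata
from charrqg.genoqc import GenotypeMatrix


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally complete breeding-programme simulation."""
    cfg = synthdata.SimConfig(
        seed=42,
        n_snps=400,
        n_families=16,
        family_size_range=(12, 18),
        n_intermediate_families=24,
    )
    return synthdata.simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_genotypes(calls, populations=None, families=None, chrom=None, pos=None):
    """Helper to build a GenotypeMatrix from a plain 0/1/2 array."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    return GenotypeMatrix(
        animal_ids=np.array([f"a{i}" for i in range(n)], dtype=object),
        snp_map=pd.DataFrame(
            {
                "snp": [f"s{j}" for j in range(m)],
                "chrom": chrom if chrom is not None else ["chr01"] * m,
                "pos": pos if pos is not None else list(range(1, m + 1)),
            }
        ),
        calls=calls,
        populations=None if populations is None else np.asarray(populations, object),
        families=None if families is None else np.asarray(families, object),
    )


@pytest.fixture
def geno_factory():
    return make_genotypes
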