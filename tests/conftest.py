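import numpy as np
import pandas as pd
import pytest

from grazescan.io import GenotypeMatrix
from grazescan.simulate import SimConfig, simulate_dataset


def make_genotypes(dosages, chrom=None, pos=None, pops=None, sites=None):
    """Hand-built GenotypeMatrix for small fixtures."""
    d = np.asarray(dosages, dtype=np.int8 if np.asarray(dosages).dtype.kind in "iu" else float)
    n, L = d.shape
    loci = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * L,
            "pos": pos if pos is not None else np.arange(1, L + 1) * 100,
            "ref": ["A"] * L,
            "alt": ["T"] * L,
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "population": pops if pops is not None else ["p1"] * n,
            "site": sites if sites is not None else ["s1"] * n,
        }
    )
    return GenotypeMatrix(d, loci, individuals)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic study shared by read-only tests."""
    cfg = SimConfig(
        n_pops=8,
        n_per_pop=10,
        n_loci=500,
        n_chrom=4,
        chrom_length_bp=20_000_000,
        n_adaptive=10,
        seed=42,
    )
    return simulate_dataset(cfg)
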