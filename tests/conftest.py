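import numpy as np
import pandas as pd
import pytest

from beefgwas import formats_io as fio
from beefgwas.formats_io import GenotypeMatrix, Variant
from beefgwas.synthetic_data import SimConfig, simulate_dataset


def make_genotypes(dosages, chrom="1", spacing=1000, samples=None, start=10_000):
    """GenotypeMatrix from a plain (n_samples x n_variants) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    variants = [
        Variant(id=f"v{j + 1}", chrom=chrom, pos=start + j * spacing)
        for j in range(m)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def make_pheno(samples, **trait_values):
    n = len(samples)
    df = pd.DataFrame({"sample_id": samples})
    df["year"] = [2007 + (i % 4) for i in range(n)]
    df["breed_group"] = [1 + (i % 6) for i in range(n)]
    for k, v in trait_values.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def small_dataset():
    """One small but complete synthetic dataset for structural tests."""
    cfg = SimConfig(
        n_samples=220,
        n_sensory=160,
        n_variants=600,
        n_chromosomes=2,
        n_genes=30,
        qtl_spec=[],
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """One replicate at the full default study conditions."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset_qc(default_dataset):
    g, _ = fio.qc_filter(default_dataset.genotypes)
    return default_dataset, g
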