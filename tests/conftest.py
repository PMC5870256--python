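"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from adaptprs.genio import GenotypeMatrix
from adaptprs.simdata import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small structured cohort with planted selection and annotation."""
    cfg = SimConfig(n_populations=10, n_per_pop=30, n_variants=1200,
                    n_chromosomes=6, n_causal=60, selection_gradient=0.4,
                    missing_rate=0.01, seed=42)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """A small cohort under the global null (no selection)."""
    cfg = SimConfig(n_populations=8, n_per_pop=25, n_variants=800,
                    n_chromosomes=4, n_causal=40, selection_gradient=0.0,
                    missing_rate=0.01, seed=7)
    return simulate_all(cfg)


def toy_genotypes(dosages, chrom=None, pos=None, site_ids=None):
    """Build a GenotypeMatrix from a raw dosage array with minimal metadata."""
    d = np.asarray(dosages, dtype=np.float32)
    n, m = d.shape
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "ref": "A", "alt": "G",
    })
    samples = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "site_id": site_ids if site_ids is not None else ["X"] * n,
    })
    return GenotypeMatrix(d, variants, samples)


@pytest.fixture
def toy_factory():
    return toy_genotypes
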