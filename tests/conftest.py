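import numpy as np
import pandas as pd
import pytest

from mitocoherence import (
    CohortConfig,
    GeneCatalog,
    TissueSpec,
    build_index_table,
    generate_cohort,
)


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    """Three mtDNA genes, three nuclear-mito genes, regulator/ISR/proliferation sets."""
    return GeneCatalog(
        mtdna_genes=frozenset({"MT-A", "MT-B", "MT-C"}),
        mito_nuclear_genes=frozenset({"NM1", "NM2", "NM3"}),
        named_sets={
            "isr": frozenset({"ATF4", "ATF5", "DDIT3", "GDF15"}),
            "proliferation": frozenset({"KI67", "TOP2A", "RRM2"}),
            "PPARGC1A": frozenset({"PPARGC1A"}),
        },
    )


@pytest.fixture
def tiny_profile() -> pd.Series:
    """One sample: mtDNA sums to 250k of a 1e6 total."""
    genes = ["MT-A", "MT-B", "MT-C", "NM1", "NM2", "NM3",
             "ATF4", "ATF5", "DDIT3", "GDF15", "KI67", "TOP2A", "RRM2", "OTH1"]
    values = [100_000, 100_000, 50_000, 60_000, 50_000, 40_000,
              5_000, 5_000, 5_000, 5_000, 10, 20, 30, 579_940]
    return pd.Series(values, index=genes, dtype=float)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject, 4-tissue cohort reused by several modules (seeded)."""
    tissues = (
        TissueSpec("brain_a", "brain", mu=0.5, nu=0.12, lam=0.5, sigma=0.7,
                   proliferation=0.1, beta=0.5),
        TissueSpec("brain_b", "brain", mu=0.45, nu=0.11, lam=0.5, sigma=0.7,
                   proliferation=0.1),
        TissueSpec("body_a", "body", mu=0.2, nu=0.1, lam=0.1, sigma=0.9,
                   proliferation=0.6, beta=-0.5, missing=0.1),
        TissueSpec("body_b", "body", mu=0.1, nu=0.08, lam=0.1, sigma=0.9,
                   proliferation=0.8),
    )
    config = CohortConfig(n_subjects=60, tissues=tissues, n_mtdna=8,
                          n_mito_nuclear=40, n_other=200, seed=42)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_index_table(small_cohort) -> pd.DataFrame:
    return build_index_table(
        small_cohort.expression, small_cohort.samples, small_cohort.catalog
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
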