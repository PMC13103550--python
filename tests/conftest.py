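import numpy as np
import pandas as pd
import pytest

from dimorphix.synthetic_cohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest noisy cohort shared across read-only tests."""
    spec = CohortSpec(
        n_f_sle=60,
        n_f_hc=20,
        n_m_sle=41,
        n_m_hc=7,
        n_rna=900,
        n_promoter=500,
        n_gene_meth=500,
        n_protein=400,
        n_protein_x=20,
        n_marker_genes=120,
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    spec = CohortSpec(
        n_f_sle=12,
        n_f_hc=6,
        n_m_sle=12,
        n_m_hc=4,
        n_rna=300,
        n_promoter=200,
        n_gene_meth=200,
        n_protein=150,
        n_protein_x=10,
        n_marker_genes=60,
        zero_noise=True,
        seed=5,
    )
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
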