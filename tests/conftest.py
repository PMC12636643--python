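import numpy as np
import pandas as pd
import pytest

from csfprognostics.matrix import AbundanceMatrix
from csfprognostics.synthetic import SimConfig, generate_cohort, generate_proteome


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_subjects=60, n_proteins=80, n_batches=4, n_modules=3,
                     module_size=10, ebm_n_biomarkers=5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    meta, truth = generate_cohort(small_config)
    m, truth = generate_proteome(meta, truth, small_config)
    return meta, m, truth


def make_matrix(values, mask=None, scale="log2") -> AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return AbundanceMatrix(
        values=values, mask=np.asarray(mask, dtype=bool),
        protein_ids=[f"p{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        scale=scale)
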