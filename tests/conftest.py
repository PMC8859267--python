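import logging

import numpy as np
import pandas as pd
import pytest

from m6apattern import ExpressionMatrix, GeneratorConfig, generate_cohort
from m6apattern.io import combat_correct, fpkm_to_tpm, log2_transform

logging.getLogger("m6apattern").setLevel(logging.ERROR)


def small_config(**overrides) -> GeneratorConfig:
    """A fast, fully planted generator configuration for unit tests."""
    base = dict(
        n_samples=120,
        cluster_sizes=(40, 40, 40),
        n_cohorts=2,
        n_genes=300,
        n_de=120,
        n_prognostic=40,
        n_panels=2,
        panel_size=10,
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_logm(small_bundle):
    m = log2_transform(fpkm_to_tpm(small_bundle.expression))
    return combat_correct(m, small_bundle.clinical.table["cohort"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, genes=None, samples=None, unit="LOG2") -> ExpressionMatrix:
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)
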