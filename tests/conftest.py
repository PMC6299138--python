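"""Shared fixtures: small synthetic cohorts and random generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from immunemap.simulate import CohortConfig, generate_cohort
from immunemap.types import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A reduced cohort that keeps unit tests fast."""
    return CohortConfig(
        n_patients=6,
        truncal_mean=12.0,
        private_mean=8.0,
        decoy_mean=3.0,
        n_clones_min=100,
        n_clones_max=400,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-parameter cohort used by end-to-end checks."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_expression(rng: np.random.Generator, n_genes: int, n_samples: int) -> ExpressionMatrix:
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{j:02d}" for j in range(n_samples)]
    vals = rng.lognormal(2.0, 1.0, size=(n_genes, n_samples))
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
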