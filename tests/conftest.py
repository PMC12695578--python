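import numpy as np
import pytest

from triadpoe import SimConfig, assemble_triads, simulate_triads
from triadpoe.simulate import genotype_triples


@pytest.fixture(scope="session")
def null_study():
    """200 clean triads simulated under no parent-of-origin effect."""
    dataset, covariates, truth = simulate_triads(
        SimConfig(n_triads=200, q=0.3, baseline_b=0.05, seed=101))
    return dataset, covariates, truth


@pytest.fixture(scope="session")
def maternal_study():
    """300 triads with a maternally transmitted risk allele (rr_m=2)."""
    dataset, covariates, truth = simulate_triads(
        SimConfig(n_triads=300, q=0.3, baseline_b=0.05, rr_m=2.0, seed=202))
    return dataset, covariates, truth


@pytest.fixture(scope="session")
def fixed_200_triples():
    """A frozen 200-triad genotype-triple array (maternal effect, q=0.3)."""
    dataset, _, _ = simulate_triads(
        SimConfig(n_triads=200, q=0.3, baseline_b=0.05, rr_m=2.0, rr_f=1.0, seed=777))
    return genotype_triples(dataset)


@pytest.fixture(scope="session")
def null_triads(null_study):
    dataset, covariates, _ = null_study
    return assemble_triads(dataset, covariates)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
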