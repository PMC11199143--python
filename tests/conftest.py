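import numpy as np
import pytest

from traitdrift import (
    DemographyConfig,
    build_architecture,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def tiny_config() -> DemographyConfig:
    """Desk-scale scenario: ~190 causal SNPs, ~25 ms per replicate."""
    return DemographyConfig(
        N0=2000,
        N=400,
        T=200,
        genome_length_bp=200_000,
        genome_length_morgans=0.002,
        causal_mutation_rate=2e-8,
        n_sample_ref=100,
        n_sample_bot=100,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_genotypes(tiny_config)


@pytest.fixture(scope="session")
def tiny_arch(tiny_dataset):
    return build_architecture(tiny_dataset, s=-1.0, h2_target=0.5, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
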