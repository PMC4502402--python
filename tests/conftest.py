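import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from nucdyn import NucleosomeDynamics, SyntheticConfig
from nucdyn.simulate import build_truth, sample_reads

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> SyntheticConfig:
    """A seconds-scale genome for unit tests: one 60 kb chromosome, 12 genes."""
    defaults = dict(
        n_chromosomes=1,
        chrom_length=60_000,
        n_genes=12,
        depth=30_000,
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    return build_truth(small_config())


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return {c: sample_reads(small_truth, c) for c in small_truth.conditions}


@pytest.fixture(scope="session")
def default_model():
    """Full-scale synthetic model at the generator's default study conditions."""
    return NucleosomeDynamics.from_synthetic(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_fit(default_model):
    return default_model.fit()
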