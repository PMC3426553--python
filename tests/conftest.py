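import pytest
from hypothesis import HealthCheck, settings

from rtevolve import EvolutionConfig, ReferenceGene, screening_scenario, simulate_library

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def reference():
    """783-nt synthetic target gene (the size of the dCK coding sequence)."""
    return ReferenceGene.random(783, seed=20260927)


@pytest.fixture(scope="session")
def big_library(reference):
    """10,000 lineages through 16 cycles at 1.14e-4/nt/cycle, default spectrum.

    The workhorse fixture for the Monte-Carlo mean, dispersion, spectrum and
    positional-law checks; built once per session.
    """
    cfg = EvolutionConfig(mutation_rate=1.14e-4, generations=16,
                          population_size=10_000, seed=1409)
    return simulate_library(cfg, reference)


@pytest.fixture(scope="session")
def screen_scenario():
    """Primary screen: 76 clones, 6 implanted sensitizers, 3 experiments."""
    return screening_scenario(seed=77)
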