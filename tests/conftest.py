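import numpy as np
import pytest

from hetwgp.simulator import SimScenario, simulate_dataset


def tiny_scenario(**overrides):
    """A mechanically complete but very small generative configuration.

    Mutation is raised well above the study conditions so that a short
    drift phase yields enough polymorphic loci; tests using this fixture
    exercise machinery, not the study's population-genetic regime.
    """
    base = dict(
        n_founders=30,
        n_generations=120,
        expansion_size=120,
        n_chromosomes=2,
        loci_per_chromosome=250,
        mutation_rate=2e-3,
        n_qtl=5,
        n_markers=60,
        n_v_levels=8,
        alpha_v=3.0,
    )
    base.update(overrides)
    return SimScenario(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(tiny_scenario(), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
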