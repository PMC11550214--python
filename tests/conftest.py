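import numpy as np
import pytest

from biokin import ExposureScenario, FitConfig, KineticParameters


@pytest.fixture
def scenario():
    """48 h exposure followed by 48 h depuration in clean medium."""
    return ExposureScenario(c_exposure=1.0, t_e=48.0, t_total=96.0)


@pytest.fixture
def slow_params():
    """Slow aquatic kinetics (Ag in daphnids): far from plateau at t_e."""
    return KineticParameters(k1=0.196, k2=0.033)


@pytest.fixture
def fast_config():
    """Small GA profile for unit tests where speed matters more than the
    last digits of convergence."""
    return FitConfig(
        population_size=150,
        steady_fitness_generations=60,
        max_generations=800,
        seed=0,
    )


def random_valid_params(rng: np.random.Generator, with_sf: bool = False) -> KineticParameters:
    """Log-uniform rate constants in physically plausible ranges."""
    k1 = 10.0 ** rng.uniform(-2, 3)
    k2 = 10.0 ** rng.uniform(-2, 1)
    sf = rng.uniform(0.0, 1.0) if with_sf else 0.0
    return KineticParameters(k1=k1, k2=k2, sf=sf)
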