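import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def blosum62():
    from memsa import load_matrix

    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def default_gaps():
    from memsa import GapModel

    return GapModel()


@pytest.fixture(scope="session")
def small_family():
    """A 3-helix, 6-member family with recorded truth."""
    from memsa.synthetic import FamilySimulationParams, simulate_family

    return simulate_family(
        FamilySimulationParams(n_sequences=6, n_helices=3, rng_seed=11)
    )


@pytest.fixture(scope="session")
def default_family():
    """One family at the headline study conditions (K=7, n=8, ~50% identity)."""
    from memsa.synthetic import FamilySimulationParams, simulate_family

    return simulate_family(FamilySimulationParams(rng_seed=1))
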