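import numpy as np
import pytest

from hkblearn import (
    PotentialParams,
    LearningTerm,
    SimulationConfig,
    SkeletonCoefficients,
    bistable_schedule,
    multistable_schedule,
)


@pytest.fixture
def bistable0():
    return bistable_schedule(0.0)


@pytest.fixture
def multistable0():
    return multistable_schedule(0.0)


@pytest.fixture
def quiet_config():
    """Noise-free integration config."""
    return SimulationConfig(noise_q=0.0, seed=0)


@pytest.fixture
def noisy_config():
    return SimulationConfig(noise_q=0.3, seed=0)


def random_params(rng: np.random.Generator) -> PotentialParams:
    """A random valid parameter set for property tests."""
    n = rng.integers(1, 6)
    a = tuple(rng.uniform(-4, 4, size=n))
    if rng.random() < 0.5:
        learning = None
    else:
        learning = LearningTerm(
            c=float(rng.uniform(0, 3)),
            kappa=float(rng.uniform(0, 9)),
            psi_deg=float(rng.uniform(1, 180)),
        )
    return PotentialParams(skeleton=SkeletonCoefficients(a), learning=learning)
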