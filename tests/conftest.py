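import dataclasses

import numpy as np
import pytest

from shoalstress.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study design for fast unit tests (not the default study)."""
    return dataclasses.replace(
        SimulationConfig(), n_groups=4, n_frames=30
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_frame(rng: np.random.Generator, n_fish: int = 7,
                 length: float = 45.0, width: float = 25.0) -> np.ndarray:
    """Uniform-random fish positions inside the tank footprint."""
    out = np.empty((n_fish, 2))
    out[:, 0] = rng.uniform(0, length, n_fish)
    out[:, 1] = rng.uniform(0, width, n_fish)
    return out
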