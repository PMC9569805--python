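import pytest

from splicedyn.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default-sized synthetic dataset with zero expression noise."""
    return simulate_dataset(SimulationConfig(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-sized synthetic dataset with the default noise level."""
    return simulate_dataset(SimulationConfig(seed=12))
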