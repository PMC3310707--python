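import numpy as np
import pytest

from frcsim import (
    LatticeConfig,
    NetworkParams,
    SimulationConfig,
    WeightParams,
    build_network,
)


@pytest.fixture(scope="session")
def small_lattice() -> LatticeConfig:
    """A small cube for cheap structural tests."""
    return LatticeConfig(side_length=6)


@pytest.fixture(scope="session")
def dense_net(small_lattice):
    """A reproducible dense network at moderate density on the small cube."""
    rng = np.random.default_rng(1234)
    return build_network(
        NetworkParams(f_frc=0.05, mode="dense"), WeightParams(), small_lattice, rng
    )


@pytest.fixture(scope="session")
def empty_net(small_lattice):
    rng = np.random.default_rng(99)
    return build_network(NetworkParams(f_frc=0.0), WeightParams(), small_lattice, rng)


@pytest.fixture()
def small_sim(small_lattice) -> SimulationConfig:
    """Short simulation config for engine tests."""
    return SimulationConfig(
        lattice=small_lattice,
        network=NetworkParams(f_frc=0.05, mode="dense"),
        steps_max=60,
        runs_per_network=3,
        networks_per_setting=2,
        master_seed=7,
    )
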