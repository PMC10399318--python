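import numpy as np
import pytest
from hypothesis import settings

import beadchain as bc

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ff_default() -> bc.ForceField:
    return bc.ForceField()


@pytest.fixture(scope="session")
def ff_calibrated() -> bc.ForceField:
    return bc.study_forcefield("calibrated")


@pytest.fixture(scope="session")
def study_topo(ff_default) -> bc.ChainTopology:
    return bc.study_topology(forces=ff_default)


@pytest.fixture()
def small_topo(ff_default) -> bc.ChainTopology:
    """A 3-bead chain (7 mobile particles) for cheap dynamics tests."""
    chain = bc.ChainSpec(n_beads=3, anchor_separation=0.04)
    return bc.build_topology(chain, bc.BeadSpec(), ff_default)


def single_particle_topology(mass: float, radius: float = 1e-3) -> bc.ChainTopology:
    """One free mobile particle, no bonds or anchors.

    Not a buildable chain; used for single-bead calibration-style tests
    (terminal velocity, overdamped stationary distribution).
    """
    empty2 = np.empty((0, 2), dtype=np.int64)
    empty3 = np.empty((0, 3), dtype=np.int64)
    empty = np.empty(0)
    return bc.ChainTopology(
        kinds=["bead"], radii=np.array([radius]), masses=np.array([mass]),
        positions=np.zeros((1, 3)),
        linear_bonds=empty2, linear_k=empty, linear_rest=empty,
        angular_bonds=empty3, angular_k=empty,
        string_bonds=empty2, string_k=empty, string_rest=empty,
    )


@pytest.fixture(scope="session")
def short_chain_run(ff_calibrated) -> bc.Trajectory:
    """A short seeded run of a small chain, shared by I/O and analysis tests."""
    chain = bc.ChainSpec(n_beads=3, anchor_separation=0.04)
    topo = bc.build_topology(chain, bc.BeadSpec(), ff_calibrated)
    forcing = bc.ForcingModel("laplace", kr=ff_calibrated.kr, seed=7)
    config = bc.SimulationConfig(n_steps=3000, equilibration_steps=500,
                                 record_stride=5, seed=7)
    return bc.run_simulation(topo, ff_calibrated, forcing, config)
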