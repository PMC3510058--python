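import numpy as np
import pytest

from aggkin.synthetic_data import (ScenarioScript, build_ideal_sheet,
                                   build_random_coil, script_trajectory)


@pytest.fixture(scope="session")
def parallel_sheet5():
    return build_ideal_sheet(5, "parallel")


@pytest.fixture(scope="session")
def antiparallel_sheet2():
    return build_ideal_sheet(2, "antiparallel")


@pytest.fixture(scope="session")
def coil20():
    return build_random_coil(20, 200.0, 10.0, seed=11)


@pytest.fixture(scope="session")
def growth8():
    script = ScenarioScript.growth(8)
    traj, partitions, events = script_trajectory(script)
    return traj, partitions, events


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
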