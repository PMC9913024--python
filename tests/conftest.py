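import numpy as np
import pytest

import fpscenarios as fp


@pytest.fixture(scope="session")
def small_config():
    return fp.SimulationConfig(n_countries=5, n_samples=60, seed=11)


@pytest.fixture(scope="session")
def small_trajectories(small_config):
    return fp.generate_trajectories(small_config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A complete synthetic input bundle on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = fp.SimulationConfig(n_countries=6, n_samples=80, seed=3)
    paths = fp.write_bundle(config, outdir)
    return outdir, paths, config


@pytest.fixture
def hand_trajectory_set():
    """1 country, 3 samples, 2 years, with hand-checkable values.

    Per-sample demand satisfied: 2019 -> (0.6, 0.5, 0.8);
    2030 -> (0.8, 0.6, 0.45/0.55); changes -> (0.2, 0.1, 0.45/0.55 - 0.8).
    """
    values = np.array(
        [
            [
                [[0.30, 0.10, 0.10], [0.40, 0.05, 0.05]],
                [[0.20, 0.10, 0.10], [0.30, 0.10, 0.10]],
                [[0.40, 0.05, 0.05], [0.45, 0.05, 0.05]],
            ]
        ]
    )
    return fp.TrajectorySet(countries=("C001",), years=(2019, 2030), values=values)
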