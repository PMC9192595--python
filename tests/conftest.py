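import numpy as np
import pytest

import quadfret as qf


@pytest.fixture(scope="session")
def telg5_model():
    return qf.construct_model("TelG5")


@pytest.fixture(scope="session")
def telg5_dataset(telg5_model):
    """Small mixed docked/dynamic TelG5 dataset with ground truth."""
    cfg = qf.SimulationConfig(
        model=telg5_model, n_molecules=40, duration=100.0, seed=123
    )
    return qf.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def telg5_trajectories(telg5_dataset):
    return [qf.compute_fret(t) for t in telg5_dataset]


def make_trajectory(values, frame_interval=0.1, molecule_id="t"):
    values = np.asarray(values, dtype=float)
    return qf.FretTrajectory(
        molecule_id=molecule_id,
        efficiency=values,
        frame_interval=frame_interval,
        valid_until=values.size,
    )
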