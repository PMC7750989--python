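import numpy as np
import pytest

from gulpflow import simulate, trajectory


@pytest.fixture(scope="session")
def default_trial():
    """One seeded default trial with esophageal transport."""
    return simulate.generate_trial(seed=42, include_swallowing=True)


@pytest.fixture(scope="session")
def default_velocity(default_trial):
    return trajectory.differentiate(default_trial.trajectory)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def straight_trajectory(n=60, frame_rate=300.0, head_length=70.0, esoph=56.0, step_mm=1.0):
    """Monotone rostrocaudal path helper used across test modules."""
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * step_mm
    return trajectory.Trajectory.from_mm(pos, head_length, esoph, frame_rate)
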