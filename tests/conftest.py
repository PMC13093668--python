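import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from metastable import (DEFAULT_R_ANGLE_DEG, LangevinConfig,
                        ThreeWellPotential, axis_vector, gaussian_filter,
                        project_axis, project_path, simulate_langevin)


@pytest.fixture(scope="session")
def default_potential():
    return ThreeWellPotential()


@pytest.fixture(scope="session")
def toy_traj(default_potential):
    """Default-length (1e6 frame) toy trajectory, shared across tests."""
    cfg = LangevinConfig(seed=1)
    return simulate_langevin(default_potential, cfg)


@pytest.fixture(scope="session")
def toy_projections(default_potential, toy_traj):
    """s, x and r projections of the shared toy trajectory."""
    s = project_path(toy_traj, default_potential.path_waypoints)
    x = toy_traj[:, 0]
    r = project_axis(toy_traj, axis_vector(DEFAULT_R_ANGLE_DEG))
    return {"s": s, "x": x, "r": r,
            "x_filtered": gaussian_filter(x, window=10),
            "r_filtered": gaussian_filter(r, window=10)}


@pytest.fixture(scope="session")
def toy_traj_short(default_potential):
    """Cheap 5e4-frame trajectory for smoke-level checks."""
    cfg = LangevinConfig(n_steps=500_000, seed=4)
    return simulate_langevin(default_potential, cfg)
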