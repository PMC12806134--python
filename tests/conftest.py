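import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from memasym import assign_leaflets, recenter_frames
from memasym.synthetic import BilayerSpec, LeafletSpec, generate_bilayer_trajectory

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bilayer200():
    """A 200-frame default-composition bilayer with ground truth, recentred."""
    spec = BilayerSpec(seed=20240, water_count=400)
    traj, truth = generate_bilayer_trajectory(spec, 200)
    traj = recenter_frames(traj)
    return traj, truth, spec


@pytest.fixture(scope="session")
def bilayer200_leaflets(bilayer200):
    traj, _truth, _spec = bilayer200
    return assign_leaflets(traj)


@pytest.fixture(scope="session")
def tiny_bilayer():
    """A fast 10-lipid-per-leaflet, 5-frame bilayer for unit tests."""
    spec = BilayerSpec(
        outer=LeafletSpec({"PC": 0.6, "CHOL": 0.4}, 10),
        inner=LeafletSpec({"PE": 0.5, "PC": 0.5}, 10),
        water_count=40,
        seed=11,
    )
    traj, truth = generate_bilayer_trajectory(spec, 5)
    return recenter_frames(traj), truth, spec


@pytest.fixture(scope="session")
def quiescent_waters():
    """A small trajectory whose waters never approach the membrane interior."""
    spec = BilayerSpec(
        outer=LeafletSpec({"PC": 1.0}, 9),
        inner=LeafletSpec({"PC": 1.0}, 9),
        water_count=30,
        seed=77,
    )
    traj, truth = generate_bilayer_trajectory(spec, 80)
    return recenter_frames(traj), truth


def reflect_z(traj):
    """z -> -z copy of a trajectory (shared test helper)."""
    from memasym.trajectory import Frame, Trajectory

    frames = []
    for fr in traj.frames:
        c = fr.coords.copy()
        c[:, 2] = -c[:, 2]
        frames.append(Frame(time=fr.time, box=fr.box.copy(), coords=c))
    return Trajectory(topology=traj.topology, frames=frames, dt=traj.dt)


@pytest.fixture
def z_reflect():
    return reflect_z
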