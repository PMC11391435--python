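import numpy as np
import pytest

from mdcompare.model_io import Atom, Topology, Trajectory
from mdcompare.synthetic_data import SyntheticSpec, build_toy_topology


@pytest.fixture(scope="session")
def toy_spec() -> SyntheticSpec:
    return SyntheticSpec(residues_per_chain=10, replicates_per_state=2,
                         frames_per_replicate=20, seed=7)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    """(Topology, reference coords) of a small two-helix complex."""
    return build_toy_topology(toy_spec)


@pytest.fixture
def two_particle_topology():
    """Two isolated charged LJ particles on separate residues/chains."""
    atoms = [
        Atom(0, "X1", "C", 0, "LIG", "A", partial_charge=1.0,
             lj_sigma=3.0, lj_epsilon=0.5),
        Atom(1, "X2", "C", 1, "LIG", "B", partial_charge=-1.0,
             lj_sigma=3.0, lj_epsilon=0.5),
    ]
    return Topology(atoms=atoms)


def make_trajectory(topology: Topology, frames: np.ndarray,
                    dt: float = 1.0) -> Trajectory:
    frames = np.asarray(frames, dtype=float)
    times = dt * np.arange(1, frames.shape[0] + 1)
    return Trajectory(topology, frames, times)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def axis_angle_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def grid_search_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                         rng: np.random.Generator,
                         n_coarse: int = 20000) -> float:
    """Coarse-to-fine rotation search oracle, independent of the SVD path."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)

    def rmsd_of(rot):
        return np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1)))

    best_rot, best = np.eye(3), rmsd_of(np.eye(3))
    for _ in range(n_coarse):
        rot = random_rotation(rng)
        r = rmsd_of(rot)
        if r < best:
            best_rot, best = rot, r
    for scale in (0.1, 0.02, 0.004, 0.0008):
        for _ in range(2000):
            rot = axis_angle_rotation(rng.normal(size=3),
                                      scale * rng.normal()) @ best_rot
            r = rmsd_of(rot)
            if r < best:
                best_rot, best = rot, r
    return best
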