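import numpy as np
import pytest

from needleplace import SynthConfig, TriMesh, generate_nerve, sample_surface
from needleplace.synthetic import generate_trial


@pytest.fixture(scope="session")
def unit_cube() -> TriMesh:
    v = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 0, 1],
            [1, 1, 1],
            [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # front
            [1, 2, 6], [1, 6, 5],  # right
            [2, 3, 7], [2, 7, 6],  # back
            [3, 0, 4], [3, 4, 7],  # left
        ]
    )
    return TriMesh(vertices=v, faces=f, name="cube")


@pytest.fixture(scope="session")
def right_triangle() -> TriMesh:
    return TriMesh(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        faces=np.array([[0, 1, 2]]),
        name="tri",
    )


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def nerve_cloud(default_config):
    mesh, _ = generate_nerve(default_config)
    return sample_surface(mesh, 0.3)


@pytest.fixture(scope="session")
def clean_trial(default_config):
    """Zero-noise, zero-jitter synthetic trial (identity pose)."""
    return generate_trial(default_config, "trial_000", seed=1)


def random_surface_cloud(mesh: TriMesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted random sampling; lattice-free (used as ICP test input)."""
    tri = mesh.triangles
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    fi = rng.choice(len(tri), n, p=areas / areas.sum())
    u, v = rng.random(n), rng.random(n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    return tri[fi, 0] + u[:, None] * (tri[fi, 1] - tri[fi, 0]) + v[:, None] * (tri[fi, 2] - tri[fi, 0])


def rotation_angle_deg(R: np.ndarray) -> float:
    return float(np.rad2deg(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))
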