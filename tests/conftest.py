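import numpy as np
import pytest

import saxsflex as sx
from saxsflex.topology import BeadModel


def lattice_sphere(radius: float, n_target: int = 2000) -> BeadModel:
    """Deterministic quasi-uniform bead filling of a sphere (offset cubic
    lattice), used as an analytic-form-factor oracle fixture."""
    a = (4.0 / 3.0 * np.pi * radius**3 / n_target) ** (1.0 / 3.0)
    g = np.arange(-radius, radius + a, a) + a / 2.0
    x, y, z = np.meshgrid(g, g, g)
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    pts = pts[np.sum(pts**2, axis=1) <= radius**2]
    return BeadModel(pts)


def sphere_form_factor(x: np.ndarray) -> np.ndarray:
    """Analytic uniform-sphere form factor [3(sin x - x cos x)/x^3]^2."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3) ** 2
    return out


@pytest.fixture(scope="session")
def bead_sphere_50() -> BeadModel:
    return lattice_sphere(50.0, 2000)


@pytest.fixture(scope="session")
def bead_sphere_30() -> BeadModel:
    return lattice_sphere(30.0, 2000)


@pytest.fixture(scope="session")
def two_arm_topology() -> sx.SegmentTopology:
    """Small free-hinge toy: 30-bead arm, 8-residue hinge, 12-bead arm."""
    arm1 = sx.make_toy_rigid_arm(30, 1.43 * 29, 8.0, seed=1)
    arm2 = sx.make_toy_rigid_arm(12, 1.43 * 11, 8.0, seed=2)
    return sx.build_topology([
        dict(kind="rigid", start=1, end=30, label="arm1", template=arm1),
        dict(kind="flexible", start=31, end=38, label="hinge"),
        dict(kind="rigid", start=39, end=50, label="arm2", template=arm2),
    ], protein_label="toy")


@pytest.fixture(scope="session")
def small_pool(two_arm_topology) -> sx.ConformerPool:
    pool = sx.generate_pool(two_arm_topology, 60, seed=42)
    sx.compute_pool_curves(pool, sx.DEFAULT_Q_GRID)
    return pool


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
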