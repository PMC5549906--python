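"""Shared fixtures: small grid meshes and deterministic RNGs."""

import numpy as np
import pytest

from wafernoise import TriangleMesh


def grid_mesh(n: int = 11, side: float = 1.0, z=None) -> TriangleMesh:
    """Regular n x n triangulated grid over [0, side]^2 at height z."""
    coords = np.linspace(0.0, side, n)
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    x, y = gx.ravel(), gy.ravel()
    zz = np.zeros_like(x) if z is None else np.broadcast_to(z, x.shape).copy()
    idx = np.arange(n * n).reshape(n, n)
    a, b = idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel()
    c, d = idx[1:, :-1].ravel(), idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([b, d, c], axis=1)]
    )
    return TriangleMesh(np.stack([x, y, zz], axis=1), faces, name=f"grid{n}")


def noisy_grid_mesh(n: int, side: float, sigma: float, rng) -> TriangleMesh:
    """Grid mesh with Gaussian height noise (same units as side)."""
    mesh = grid_mesh(n, side)
    v = mesh.vertices.copy()
    v[:, 2] += rng.standard_normal(v.shape[0]) * sigma
    return TriangleMesh(v, mesh.faces, name=mesh.name)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix via QR."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def make_grid():
    return grid_mesh


@pytest.fixture
def make_noisy_grid():
    return noisy_grid_mesh
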