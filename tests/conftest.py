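"""Shared fixtures.

Expensive transport solves are session-scoped and shared between the module
tests and the acceptance suite; meshes are generated programmatically at
collection time so the repository carries no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from tsomt.boundary import solve_boundary_omt
from tsomt.density import uniform_density
from tsomt.interior import run_homotopy
from tsomt.mesh import build_solid_mesh, tetrahedralize


def ball_mask(radius: float, size: int | None = None) -> np.ndarray:
    """Digitized solid ball: voxel centres within ``radius`` of the middle."""
    size = size or int(2 * radius + 4)
    ax = np.arange(size) - (size - 1) / 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return X ** 2 + Y ** 2 + Z ** 2 <= radius ** 2


def ellipsoid_mask(a: float, b: float, c: float) -> np.ndarray:
    size = int(2 * max(a, b, c) + 4)
    ax = np.arange(size) - (size - 1) / 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_ball_mesh():
    """Solver-ready mesh of a radius-8 ball (a few thousand vertices)."""
    return build_solid_mesh(ball_mask(8))


@pytest.fixture(scope="session")
def small_ball_solution(small_ball_mesh):
    """Full transport solve (rho = 1, p = 8) on the small ball."""
    mesh = small_ball_mesh
    dens = uniform_density(mesh)
    bmap = solve_boundary_omt(mesh.boundary(), dens)
    vmap = run_homotopy(mesh, dens, bmap, 8)
    return mesh, dens, bmap, vmap


@pytest.fixture(scope="session")
def tiny_grid_mesh():
    """Raw 3x3x3-voxel Kuhn mesh (unnormalized, for algebraic identities)."""
    return tetrahedralize(np.ones((3, 3, 3), dtype=bool))


@pytest.fixture(scope="session")
def identity_ball_run():
    """Identity-limit study condition: radius-20 ball, ρ ≡ 1, p = 8."""
    from tsomt.mesh import coarsen_mask

    mask = ball_mask(20, 44)
    mesh = build_solid_mesh(coarsen_mask(mask, 2))
    mesh.grid_step = 2
    dens = uniform_density(mesh)
    bmap = solve_boundary_omt(mesh.boundary(), dens)
    vmap = run_homotopy(mesh, dens, bmap, 8, inner_iterations=2)
    return mesh, dens, bmap, vmap


@pytest.fixture(scope="session")
def phantom_case():
    """Default 64³ phantom through the full case pipeline (ρ̃₁, p = 8)."""
    from tsomt.phantom import PhantomSpec, make_phantom
    from tsomt.pipeline import build_case_map

    gray, labels = make_phantom(PhantomSpec(seed=0))
    return build_case_map(gray, labels)


@pytest.fixture(scope="session")
def small_phantom_problem():
    """48³ phantom mesh + density + boundary map (p-sweeps, rotations)."""
    from tsomt.density import density_from_grayscale, equalize_histogram, \
        normalize_grayscale, sample_at_vertices
    from tsomt.mesh import coarsen_mask, voxel_mask
    from tsomt.phantom import PhantomSpec, make_phantom

    gray, _ = make_phantom(PhantomSpec(size=48, seed=3))
    mask = voxel_mask(gray)
    mesh = build_solid_mesh(coarsen_mask(mask, 2))
    mesh.grid_step = 2
    phi = equalize_histogram(normalize_grayscale(gray[..., 0], mask), mask)
    dens = density_from_grayscale(sample_at_vertices(phi, mesh), mesh)
    bmap = solve_boundary_omt(mesh.boundary(), dens)
    return mesh, dens, bmap


@pytest.fixture(scope="session")
def random_blob_mesh():
    """Genus-zero random blob mesh for property tests."""
    rng = np.random.default_rng(7)
    mask = ball_mask(6, 20)
    noise = rng.random(mask.shape) < 0.12
    from tsomt.mesh import ensure_genus_zero
    return tetrahedralize(ensure_genus_zero(mask | (noise & ball_mask(8, 20))))
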