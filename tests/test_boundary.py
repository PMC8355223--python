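"""Spherical area-preserving boundary parameterization."""

import numpy as np
import pytest

from tsomt.boundary import (area_energy, area_laplacian, area_stretch_factor,
                            initial_spherical_map, inverse_stereographic,
                            solve_boundary_omt, spherical_folds, stereographic,
                            triangle_areas)
from tsomt.density import DensityField, uniform_density, _field_from_rho
from tsomt.mesh import SurfaceMesh, build_solid_mesh

from conftest import ellipsoid_mask


class TestStereographic:
    @pytest.mark.parametrize("point,expected", [
        ((0, 0, -1), 0 + 0j),
        ((1, 0, 0), 1 + 0j),
        ((0, 1, 0), 0 + 1j),
    ])
    def test_chart_values(self, point, expected):
        assert stereographic(np.array([point], float))[0] == pytest.approx(expected)

    def test_north_pole_maps_to_infinity(self):
        h = stereographic(np.array([[0.0, 0.0, 1.0]]))
        assert np.isinf(h[0])
        assert np.allclose(inverse_stereographic(h)[0], (0, 0, 1))

    def test_round_trip_random_unit_vectors(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal((100, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        back = inverse_stereographic(stereographic(g))
        assert np.abs(back - g).max() < 1e-12


def _two_triangle_surface(points):
    """Open two-triangle patch sharing edge (0, 1)."""
    return SurfaceMesh(vertices=points,
                       triangles=np.array([[0, 1, 2], [1, 0, 3]]),
                       vertex_map=np.arange(4))


def _uniform_field(surface):
    nB = surface.n_vertices
    areas = surface.areas()
    star = np.zeros(nB)
    np.add.at(star, surface.triangles.ravel(), np.repeat(areas, 3))
    return DensityField(rho_vertex=np.ones(nB), rho_tet=np.ones(0),
                        rho_face=np.ones(len(surface.triangles)),
                        local_mass=np.zeros(nB), local_area=star / 3.0)


class TestAreaStretch:
    def test_rigid_map_has_unit_stretch(self):
        pts = np.array([[0., 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0]])
        surf = _two_triangle_surface(pts)
        dens = _uniform_field(surf)
        sigma = area_stretch_factor(surf, pts + 5.0, dens, normalized=False)
        assert sigma == pytest.approx([1.0, 1.0])

    def test_halved_image_area_doubles_stretch(self):
        pts = np.array([[0., 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0]])
        surf = _two_triangle_surface(pts)
        dens = _uniform_field(surf)
        shrunk = pts.copy()
        shrunk[:, 1] *= 0.5
        sigma = area_stretch_factor(surf, shrunk, dens, normalized=False)
        assert sigma == pytest.approx([2.0, 2.0])

    def test_matches_cross_product_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((4, 3))
        img = rng.standard_normal((4, 3))
        surf = _two_triangle_surface(pts)
        dens = _uniform_field(surf)
        sigma = area_stretch_factor(surf, img, dens, normalized=False)
        for f, tri in enumerate(surf.triangles):
            a, b, c = pts[tri]
            src = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            a, b, c = img[tri]
            dst = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            assert sigma[f] == pytest.approx(src / dst, rel=1e-12)


class TestAreaLaplacian:
    def _equilateral_pair(self):
        # two unit equilateral triangles sharing edge (0, 1); image = source
        h = np.sqrt(3) / 2
        pts = np.array([[0., 0, 0], [1, 0, 0], [0.5, h, 0], [0.5, -h, 0]])
        surf = _two_triangle_surface(pts)
        return surf, _uniform_field(surf), pts

    def test_equilateral_hand_value(self):
        surf, dens, pts = self._equilateral_pair()
        L = area_laplacian(surf, pts, dens).toarray()
        # sigma = 1, both opposite angles 60 deg: -1/2 (cot60 + cot60) = -1/sqrt(3)
        assert L[0, 1] == pytest.approx(-1 / np.sqrt(3), rel=1e-12)

    def test_row_sums_zero_and_symmetry(self, small_ball_solution):
        mesh, dens, bmap, _ = small_ball_solution
        L = area_laplacian(mesh.boundary(), bmap.g, dens)
        assert np.abs(L.sum(axis=1)).max() < 1e-10
        assert abs(L - L.T).max() < 1e-12

    def test_zero_off_non_edges(self):
        surf, dens, pts = self._equilateral_pair()
        L = area_laplacian(surf, pts, dens).toarray()
        assert L[2, 3] == 0.0             # (2,3) is not an edge


class TestAreaEnergy:
    def test_lambda_zero_is_smoothing_term_only(self, small_ball_solution):
        mesh, dens, bmap, _ = small_ball_solution
        surf = mesh.boundary()
        L = area_laplacian(surf, bmap.g, dens)
        smooth = sum(np.linalg.norm(L @ bmap.g[:, k]) ** 2 for k in range(3))
        assert area_energy(surf, bmap.g, dens, 0.0) == pytest.approx(smooth)

    def test_alignment_vanishes_for_radial_map(self, small_ball_mesh):
        surf = small_ball_mesh.boundary()
        dens = uniform_density(small_ball_mesh)
        g = surf.vertices / np.linalg.norm(surf.vertices, axis=1, keepdims=True)
        e0 = area_energy(surf, g, dens, 0.0)
        e1 = area_energy(surf, g, dens, 10.0)
        assert e1 == pytest.approx(e0)    # alignment term is exactly zero

    def test_nonnegative(self, small_ball_solution):
        mesh, dens, bmap, _ = small_ball_solution
        rng = np.random.default_rng(4)
        g = rng.standard_normal(bmap.g.shape)
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        assert area_energy(mesh.boundary(), g, dens, 0.3) >= 0.0


class TestSolve:
    def test_ball_converges_to_unit_stretch(self, small_ball_solution):
        mesh, dens, bmap, _ = small_ball_solution
        sigma = area_stretch_factor(mesh.boundary(), bmap.g, dens)
        assert 0.99 <= sigma.mean() <= 1.01
        assert bmap.folded == 0
        assert np.abs(np.linalg.norm(bmap.g, axis=1) - 1).max() < 1e-12

    def test_energy_nonincreasing_over_accepted_iterates(self, small_ball_solution):
        _, _, bmap, _ = small_ball_solution
        assert min(bmap.energies) == pytest.approx(bmap.energies[-1], rel=0.5)
        assert bmap.energies[-1] <= bmap.energies[0]

    def test_ellipsoid_area_preservation(self):
        mesh = build_solid_mesh(ellipsoid_mask(16, 8, 8))
        dens = uniform_density(mesh)
        bmap = solve_boundary_omt(mesh.boundary(), dens, tol=1e-6)
        sigma = area_stretch_factor(mesh.boundary(), bmap.g, dens)
        assert 0.99 <= sigma.mean() <= 1.01
        assert np.percentile(np.abs(sigma - 1), 99) <= 0.1
        assert bmap.folded == 0

    def test_uniform_density_scaling_leaves_map_invariant(self, small_ball_mesh):
        mesh = small_ball_mesh
        d1 = uniform_density(mesh)
        d2 = _field_from_rho(np.full(mesh.n_vertices, 2.0), mesh)
        g1 = solve_boundary_omt(mesh.boundary(), d1).g
        g2 = solve_boundary_omt(mesh.boundary(), d2).g
        # identical up to the alignment term's relative weight
        assert np.abs(g1 - g2).max() < 5e-3

    def test_initial_harmonic_map_is_spherical(self, small_ball_mesh):
        surf = small_ball_mesh.boundary()
        g = initial_spherical_map(surf, uniform_density(small_ball_mesh))
        assert np.abs(np.linalg.norm(g, axis=1) - 1).max() < 1e-12
        # the flattening is an embedding: few (ideally no) folded triangles
        assert spherical_folds(surf, g) <= 0.01 * len(surf.triangles)

    def test_rotation_equivariance_of_result(self, small_ball_mesh):
        from scipy.stats import special_ortho_group
        mesh = small_ball_mesh
        dens = uniform_density(mesh)
        g0 = solve_boundary_omt(mesh.boundary(), dens).g
        R = special_ortho_group.rvs(3, random_state=np.random.default_rng(5))
        surf = mesh.boundary()
        rot = SurfaceMesh(vertices=surf.vertices @ R.T,
                          triangles=surf.triangles, vertex_map=surf.vertex_map)
        g1 = solve_boundary_omt(rot, dens).g
        assert np.abs(g1 - g0 @ R.T).max() < 1e-6


def test_triangle_areas_matches_heron():
    pts = np.array([[0., 0, 0], [3, 0, 0], [0, 4, 0]])
    assert triangle_areas(pts, np.array([[0, 1, 2]]))[0] == pytest.approx(6.0)
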