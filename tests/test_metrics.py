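"""Transport-quality and segmentation metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tsomt.density import uniform_density, density_from_grayscale
from tsomt.mesh import TetMesh
from tsomt.metrics import (CLASS_LABELS, ConfusionCounts, bijectivity,
                           class_mask, conversion_loss, hausdorff, hd95,
                           segmentation_scores, stretch_ratio,
                           total_distortion, transport_cost)


def brute_hd(a, b, q):
    """All-pairs directed-percentile oracle on boundary voxels."""
    from tsomt.metrics import _boundary_points
    pa, pb = _boundary_points(a), _boundary_points(b)
    d = cdist(pa, pb)
    return max(np.percentile(d.min(axis=1), q), np.percentile(d.min(axis=0), q))


def random_mask(rng, shape=(20, 20, 20), p=0.5):
    """Random blob-ish mask (smoothed noise threshold)."""
    from scipy.ndimage import gaussian_filter
    f = gaussian_filter(rng.standard_normal(shape), 2.0)
    return f > np.quantile(f, p)


class TestTransportCost:
    def test_identity_is_zero(self, tiny_grid_mesh):
        dens = uniform_density(tiny_grid_mesh)
        assert transport_cost(tiny_grid_mesh, dens,
                              tiny_grid_mesh.vertices) == 0.0

    def test_translation_closed_form(self, tiny_grid_mesh):
        mesh = tiny_grid_mesh
        rng = np.random.default_rng(0)
        dens = density_from_grayscale(rng.random(mesh.n_vertices), mesh)
        d = np.array([0.3, -0.2, 0.5])
        expected = np.dot(d, d) * dens.local_mass.sum()
        assert transport_cost(mesh, dens, mesh.vertices + d) == \
            pytest.approx(expected, rel=1e-12)


class TestDistortionAndStretch:
    def test_mass_preserving_map_zero_distortion(self, tiny_grid_mesh):
        mesh = tiny_grid_mesh
        dens = uniform_density(mesh)
        # identity is exactly mass-preserving for rho = 1
        assert total_distortion(mesh, dens, mesh.vertices) == \
            pytest.approx(0.0, abs=1e-12)
        r, mean, sd = stretch_ratio(mesh, dens, mesh.vertices)
        assert np.allclose(r, 1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_two_tet_hand_computed_distortion(self):
        # two unit-ish tets sharing a face; image doubles the second tet
        verts = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0],
                          [0, 0, 1], [1, 1, 1.]])
        tets = np.array([[0, 1, 2, 3], [4, 1, 3, 2]])
        mesh = TetMesh(vertices=verts, tets=tets)
        vols = mesh.tet_volumes()
        assert (vols > 0).all()
        img = verts.copy()
        img[4] = verts[4] + (verts[4] - verts[1])   # stretch second tet
        ivols = mesh.tet_volumes(img)
        dens = uniform_density(mesh)
        # hand evaluation of the L1 distortion formula
        m_hat = np.zeros(5)
        v_hat = np.zeros(5)
        for t in range(2):
            for v in tets[t]:
                m_hat[v] += vols[t] / vols.sum()
                v_hat[v] += ivols[t] / ivols.sum()
        expected = 0.25 * np.abs(m_hat - v_hat).sum()
        assert total_distortion(mesh, dens, img) == pytest.approx(expected)

    def test_uniform_image_scaling_cancels(self, tiny_grid_mesh):
        mesh = tiny_grid_mesh
        rng = np.random.default_rng(1)
        dens = density_from_grayscale(rng.random(mesh.n_vertices), mesh)
        img = mesh.vertices + 0.05 * rng.standard_normal(mesh.vertices.shape)
        r1, m1, s1 = stretch_ratio(mesh, dens, img)
        r2, m2, s2 = stretch_ratio(mesh, dens, 2.5 * img)
        assert np.allclose(r1, r2)


class TestBijectivity:
    def test_no_folds_is_100(self, tiny_grid_mesh):
        folded, rate = bijectivity(tiny_grid_mesh, tiny_grid_mesh.vertices)
        assert folded == 0
        assert rate == 100.0

    def test_deliberate_vertex_swap_is_flagged(self, tiny_grid_mesh):
        mesh = tiny_grid_mesh
        img = mesh.vertices.copy()
        a, b = mesh.tets[0, 0], mesh.tets[0, 1]
        img[[a, b]] = img[[b, a]]
        folded, rate = bijectivity(mesh, img)
        assert folded >= 1
        assert rate == pytest.approx(100 * (1 - folded / mesh.n_tets))


class TestSegmentationScores:
    def test_printed_formulas(self):
        dice, sens, spec = segmentation_scores(
            ConfusionCounts(TP=8, FP=2, FN=2, TN=88))
        assert dice == pytest.approx(0.8)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(88 / 90)

    def test_perfect_prediction(self):
        dice, sens, spec = segmentation_scores(
            ConfusionCounts(TP=10, FP=0, FN=0, TN=90))
        assert (dice, sens, spec) == (1.0, 1.0, 1.0)

    def test_undefined_gives_nan(self):
        dice, _, _ = segmentation_scores(ConfusionCounts(0, 0, 0, 10))
        assert np.isnan(dice)

    def test_dice_is_one_minus_conversion_loss(self):
        rng = np.random.default_rng(2)
        a, b = random_mask(rng), random_mask(rng)
        counts = ConfusionCounts.from_masks(a, b)
        dice, _, _ = segmentation_scores(counts)
        assert dice == pytest.approx(1.0 - conversion_loss(b, a), abs=1e-14)


class TestConversionLoss:
    def test_identical_sets(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:3] = True
        assert conversion_loss(a, a) == 0.0

    def test_disjoint_sets(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert conversion_loss(a, b) == 1.0

    def test_half_overlap(self):
        a = np.zeros(40, bool)
        b = np.zeros(40, bool)
        a[:10], b[5:15] = True, True
        assert conversion_loss(a, b) == pytest.approx(0.5)

    def test_both_empty_is_zero(self):
        z = np.zeros((3, 3, 3), bool)
        assert conversion_loss(z, z) == 0.0


class TestHausdorff:
    def test_identical_masks_zero(self):
        rng = np.random.default_rng(3)
        a = random_mask(rng)
        assert hd95(a, a) == 0.0
        assert hausdorff(a, a) == 0.0

    def test_two_single_voxels(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[1, 1, 1], b[4, 5, 1] = True, True
        assert hausdorff(a, b) == pytest.approx(5.0)
        assert hd95(a, b) == pytest.approx(5.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a, b = random_mask(rng), random_mask(rng)
            assert hd95(a, b) == pytest.approx(brute_hd(a, b, 95), abs=1e-12)
            assert hausdorff(a, b) == pytest.approx(brute_hd(a, b, 100),
                                                    abs=1e-12)

    def test_hd95_not_above_hd_and_symmetric(self):
        rng = np.random.default_rng(5)
        a, b = random_mask(rng), random_mask(rng)
        assert hd95(a, b) <= hausdorff(a, b)
        assert hausdorff(a, b) == pytest.approx(hausdorff(b, a))

    def test_empty_boundary_is_infinite(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.ones((5, 5, 5), bool)
        assert np.isinf(hd95(a, b))


def test_class_masks_follow_brats_grouping():
    labels = np.arange(4).reshape(1, 1, 4)
    assert class_mask(labels, "WT").sum() == 3
    assert class_mask(labels, "TC").sum() == 2
    assert class_mask(labels, "ET").sum() == 1
    assert set(CLASS_LABELS) == {"WT", "TC", "ET"}
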