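import numpy as np
import pytest

import shapereg as sr
from shapereg.shape import EmptySurfaceError, _union_mask


def _sphere_volume(radius=10, size=32, spacing=1.0):
    c = (size - 1) / 2.0
    ax = np.arange(size)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius ** 2
    return sr.LabelVolume(mask.astype(np.int32), spacing=np.full(3, spacing))


class TestIsosurface:
    def test_single_voxel_closed_surface(self):
        lab = sr.LabelVolume(np.zeros((8, 8, 8), np.int32))
        lab.data[4, 4, 4] = 1
        mesh = sr.extract_isosurface(lab, 1)
        assert mesh.euler_characteristic() == 2
        # marching cubes clips the cube's corners; enclosed volume is a
        # fixed fraction of the voxel volume
        assert 0.1 < mesh.enclosed_volume() < 1.0

    def test_sphere_area_and_topology(self):
        lab = _sphere_volume(radius=10)
        mesh = sr.extract_isosurface(lab, 1)
        analytic = 4 * np.pi * 10 ** 2
        assert abs(mesh.surface_area() - analytic) / analytic < 0.05
        assert mesh.euler_characteristic() == 2

    def test_sphere_volume_against_analytic(self):
        lab = _sphere_volume(radius=10)
        mesh = sr.extract_isosurface(lab, 1)
        analytic = 4.0 / 3.0 * np.pi * 10 ** 3
        assert abs(mesh.enclosed_volume() - analytic) / analytic < 0.05

    def test_empty_label_rejected(self):
        lab = sr.LabelVolume(np.zeros((8, 8, 8), np.int32))
        with pytest.raises(EmptySurfaceError):
            sr.extract_isosurface(lab, 3)

    def test_nodes_in_world_coordinates(self):
        lab = _sphere_volume(radius=6, size=32, spacing=0.5)
        lab.origin = np.array([10.0, 0.0, -5.0])
        mesh = sr.extract_isosurface(lab, 1)
        center = mesh.nodes.mean(axis=0)
        expected = lab.world((np.asarray(lab.size) - 1) / 2.0)
        np.testing.assert_allclose(center, expected, atol=0.5)


class TestDecimation:
    def test_rate_achieved_within_ten_percent(self):
        mesh = sr.extract_isosurface(_sphere_volume(radius=12, size=40), 1)
        assert mesh.n_nodes > 1000
        dec = sr.decimate_mesh(mesh, 0.96)
        target = 0.04 * mesh.n_nodes
        assert abs(dec.n_nodes - target) <= 0.1 * target + 1

    def test_surviving_nodes_lie_on_original_surface(self):
        mesh = sr.extract_isosurface(_sphere_volume(radius=10), 1)
        dec = sr.decimate_mesh(mesh, 0.9)
        # half-edge collapse keeps a subset of the original node positions
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mesh.nodes).query(dec.nodes)
        assert d.max() == 0.0

    def test_tiny_mesh_returned_unchanged(self):
        mesh = sr.SurfaceMesh(nodes=np.eye(3), triangles=[[0, 1, 2]])
        with pytest.warns(UserWarning, match="too small"):
            dec = sr.decimate_mesh(mesh, 0.96)
        assert dec.n_nodes == 3

    def test_invalid_rate_rejected(self):
        mesh = sr.SurfaceMesh(nodes=np.eye(3), triangles=[[0, 1, 2]])
        with pytest.raises(ValueError):
            sr.decimate_mesh(mesh, 1.5)


class TestKappa:
    def _vol(self, mask):
        return sr.LabelVolume(mask.astype(np.int32))

    def test_identical_masks(self):
        m = np.zeros((8, 8, 8))
        m[2:5] = 1
        assert sr.kappa_statistic(self._vol(m), self._vol(m)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8))
        b = np.zeros((8, 8, 8))
        a[0], b[5] = 1, 1
        assert sr.kappa_statistic(self._vol(a), self._vol(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 1, 1))
        b = np.zeros((20, 1, 1))
        a[0:10], b[5:15] = 1, 1
        assert sr.kappa_statistic(self._vol(a), self._vol(b)) == 0.5

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = self._vol(rng.random((10, 10, 10)) > 0.6)
            b = self._vol(rng.random((10, 10, 10)) > 0.6)
            k1 = sr.kappa_statistic(a, b)
            assert k1 == sr.kappa_statistic(b, a)
            assert 0.0 <= k1 <= 1.0

    def test_both_empty_warns_zero(self):
        e = self._vol(np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning):
            assert sr.kappa_statistic(e, e) == 0.0


class TestBinaryRegister:
    @pytest.fixture(scope="class")
    def shifted_blob(self):
        c = (31.5, 31.5, 31.5)
        ax = np.arange(64)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        blob = ((x - c[0]) ** 2 / 14 ** 2 + (y - c[1]) ** 2 / 10 ** 2
                + (z - c[2]) ** 2 / 12 ** 2) <= 1.0
        fixed = sr.LabelVolume(blob.astype(np.int32))
        moving = sr.LabelVolume(np.roll(blob, 5, axis=0).astype(np.int32))
        return fixed, moving

    def test_identity_case_keeps_perfect_kappa(self):
        m = _sphere_volume(radius=8)
        t = sr.binary_register(m, m, iterations=10, n_samples=500, seed=0)
        warped = sr.resample(m, t, m)
        assert sr.kappa_statistic(m, warped) >= 0.99

    def test_known_shift_recovery(self, shifted_blob):
        fixed, moving = shifted_blob
        t = sr.binary_register(fixed, moving, iterations=30, n_samples=2000, seed=0)
        warped = sr.resample(moving, t, fixed)
        assert sr.kappa_statistic(fixed, warped) > 0.9

    def test_centroid_mapped_to_centroid(self, shifted_blob):
        fixed, moving = shifted_blob
        t = sr.binary_register(fixed, moving, iterations=30, n_samples=2000, seed=0)
        cf = np.argwhere(fixed.data > 0).mean(axis=0)
        cm = np.argwhere(moving.data > 0).mean(axis=0)
        mapped = t.apply(fixed.world(cf))
        assert np.linalg.norm(mapped - moving.world(cm)) < 2.0

    def test_empty_mask_rejected(self):
        e = sr.LabelVolume(np.zeros((8, 8, 8), np.int32))
        f = _sphere_volume(radius=3, size=8)
        with pytest.raises(ValueError):
            sr.binary_register(e, f)


class TestPropagation:
    def test_identity_and_translation(self):
        pts = np.random.default_rng(1).uniform(0, 40, (20, 3))
        np.testing.assert_array_equal(sr.propagate_landmarks(pts, sr.identity_transform()), pts)
        t = sr.translation_transform([1.0, -2.0, 3.0])
        np.testing.assert_allclose(sr.propagate_landmarks(pts, t), pts + [1, -2, 3])

    def test_matches_combined_apply_pointwise(self, random_ffd):
        t = sr.CombinedTransform(ffd=random_ffd)
        pts = np.random.default_rng(2).uniform(10, 38, (15, 3))
        np.testing.assert_array_equal(sr.propagate_landmarks(pts, t), t.apply(pts))


class TestShapePointPipeline:
    def test_extract_pools_five_surfaces_excluding_lv(self, case48):
        pts, codes = sr.extract_shape_points(case48.fixed_labels)
        assert sr.CARDIAC_LABELS["LV"] not in set(codes)
        assert set(codes) == {sr.CARDIAC_LABELS[n] for n in ("AO", "LVM", "LA", "RV", "RA")}
        assert len(pts) == len(codes)

    def test_landmarks_lie_near_label_surfaces(self, case48):
        pts, codes = sr.extract_shape_points(case48.fixed_labels)
        # every landmark voxel neighbourhood must touch its structure
        vox = np.round(case48.fixed_labels.voxel(pts)).astype(int)
        vox = np.clip(vox, 1, np.asarray(case48.fixed_labels.size) - 2)
        hits = 0
        for p, c in zip(vox, codes):
            nb = case48.fixed_labels.data[p[0] - 1:p[0] + 2, p[1] - 1:p[1] + 2,
                                          p[2] - 1:p[2] + 2]
            hits += int(np.any(nb == c))
        assert hits == len(vox)

    def test_build_shape_pairs_end_to_end(self, case48):
        pairs = sr.build_shape_pairs(case48.fixed_labels, case48.moving_labels,
                                     seed=0, iterations=25, n_samples=1500)
        assert len(pairs.p_f) == len(pairs.p_m)
        # propagated points approximate the ground-truth correspondence
        err = np.linalg.norm(pairs.p_m - case48.true_transform.apply(pairs.p_f), axis=1)
        assert err.mean() < 2.0

    def test_union_mask_merges_structures(self, case48):
        u = _union_mask(case48.fixed_labels, [1, 2, 3, 4, 5, 6])
        assert set(np.unique(u.data)) == {0, 1}
        assert u.data.sum() == (case48.fixed_labels.data > 0).sum()
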