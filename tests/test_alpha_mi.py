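import numpy as np
import pytest

import shapereg as sr
from shapereg.alpha_mi import (
    FeatureSampleSet,
    MovingFeatureModel,
    alpha_mi_value_and_gradient,
    build_topology,
    _gammas,
    _value_from_gammas,
)

from _oracles import brute_alpha_mi, brute_knn_total_distance

EXACT_CFG = sr.AlphaMIConfig(k=5, alpha=0.99, ann_error_bound=0.0)


class TestKnnTotalDistance:
    def test_hand_computed_1d_case(self):
        assert sr.knn_total_distance(np.array([[0.0], [1.0], [3.0]]), 0, 2) == 4.0

    def test_coincident_rows_zero(self):
        X = np.ones((6, 3))
        assert sr.knn_total_distance(X, 2, 4) == 0.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        vals = [sr.knn_total_distance(X, 3, k) for k in range(1, 19)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        for i in (0, 7, 29):
            np.testing.assert_allclose(sr.knn_total_distance(X, i, 5),
                                       brute_knn_total_distance(X, i, 5), rtol=1e-12)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            sr.knn_total_distance(np.zeros((4, 2)), 0, 4)


class TestAlphaMIValue:
    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 51))
            d = int(rng.integers(1, 18))
            zf = rng.normal(size=(n, d))
            zm = zf + rng.normal(0, 0.5, size=(n, d))
            s = FeatureSampleSet(points=np.zeros((n, 3)), zf=zf, zm=zm)
            v = sr.alpha_mi(s, EXACT_CFG)
            ref = brute_alpha_mi(zf, zm, 5, 0.99)
            assert abs(v - ref) < 1e-12

    def test_tiny_hand_listed_set_matches_oracle(self):
        zf = np.array([[0.0], [1.0], [2.5], [4.0]])
        zm = np.array([[0.1], [0.8], [2.7], [3.5]])
        cfg = sr.AlphaMIConfig(k=2, alpha=0.99, ann_error_bound=0.0)
        s = FeatureSampleSet(points=np.zeros((4, 3)), zf=zf, zm=zm)
        assert abs(sr.alpha_mi(s, cfg) - brute_alpha_mi(zf, zm, 2, 0.99)) < 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        zf = rng.normal(size=(40, 6))
        zm = zf + rng.normal(0, 0.3, size=(40, 6))
        s1 = FeatureSampleSet(points=np.zeros((40, 3)), zf=zf, zm=zm)
        perm = rng.permutation(40)
        s2 = FeatureSampleSet(points=np.zeros((40, 3)), zf=zf[perm], zm=zm[perm])
        np.testing.assert_allclose(sr.alpha_mi(s1, EXACT_CFG), sr.alpha_mi(s2, EXACT_CFG),
                                   rtol=1e-12)

    def test_duplication_changes_value_as_predicted(self):
        rng = np.random.default_rng(4)
        zf = rng.normal(size=(15, 3))
        zm = zf + rng.normal(0, 0.4, size=(15, 3))
        zf2 = np.concatenate([zf, zf])
        zm2 = np.concatenate([zm, zm])
        s2 = FeatureSampleSet(points=np.zeros((30, 3)), zf=zf2, zm=zm2)
        np.testing.assert_allclose(sr.alpha_mi(s2, EXACT_CFG),
                                   brute_alpha_mi(zf2, zm2, 5, 0.99), atol=1e-12)

    def test_value_finite_for_coincident_features(self):
        s = FeatureSampleSet(points=np.zeros((10, 3)),
                             zf=np.ones((10, 2)), zm=np.ones((10, 2)))
        cfg = sr.AlphaMIConfig(k=3, alpha=0.99, ann_error_bound=0.0)
        assert np.isfinite(sr.alpha_mi(s, cfg))

    def test_sqrt_product_denominator_variant(self):
        rng = np.random.default_rng(5)
        zf = rng.normal(size=(20, 4))
        zm = zf + rng.normal(0, 0.2, size=(20, 4))
        cfg = sr.AlphaMIConfig(k=5, alpha=0.99, denominator="sqrt_product",
                               ann_error_bound=0.0)
        s = FeatureSampleSet(points=np.zeros((20, 3)), zf=zf, zm=zm)
        ref = brute_alpha_mi(zf, zm, 5, 0.99, denominator="sqrt_product")
        assert abs(sr.alpha_mi(s, cfg) - ref) < 1e-12

    def test_too_few_valid_samples_raises(self):
        s = FeatureSampleSet(points=np.zeros((4, 3)), zf=np.zeros((4, 2)),
                             zm=np.zeros((4, 2)))
        with pytest.raises(sr.MetricUndefinedError):
            sr.alpha_mi(s, EXACT_CFG)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sr.AlphaMIConfig(alpha=1.2)
        with pytest.raises(ValueError):
            sr.AlphaMIConfig(k=0)
        assert sr.AlphaMIConfig(alpha=0.99).gamma(17) == pytest.approx(0.17)


class TestDiscriminability:
    def test_identity_scores_higher_than_random_warp(self, textured_volume):
        """On a textured volume the metric prefers alignment to a 5 mm warp."""
        stack = sr.assemble_feature_stack(textured_volume, (1.0,))
        rng = np.random.default_rng(6)
        pts_norm = rng.uniform(4, 27, (400, 3))
        stack_n = sr.normalize_features(stack, pts_norm)
        model = MovingFeatureModel(stack_n)
        wins = 0
        trials = 20
        for _ in range(trials):
            pts = rng.uniform(5, 26, (300, 3))
            zf = stack_n.sample(pts)
            zm_id = model.sample(pts)
            s_id = FeatureSampleSet(points=pts, zf=zf, zm=zm_id)
            ffd = sr.FFDTransform.for_domain([0, 0, 0], [31, 31, 31], 12.0)
            ffd.coefficients = rng.uniform(-5, 5, ffd.coefficients.shape)
            warped = sr.CombinedTransform(ffd=ffd).apply(pts)
            zm_w = model.sample(warped)
            s_w = FeatureSampleSet(points=pts, zf=zf, zm=zm_w)
            if sr.alpha_mi(s_id, EXACT_CFG) > sr.alpha_mi(s_w, EXACT_CFG):
                wins += 1
        assert wins >= int(0.95 * trials)


class TestAlphaMIGradient:
    @pytest.fixture()
    def gradient_problem(self, textured_volume):
        rng = np.random.default_rng(7)
        stack = sr.assemble_feature_stack(textured_volume, (1.0,))
        stack_n = sr.normalize_features(stack, rng.uniform(4, 27, (400, 3)))
        model = MovingFeatureModel(stack_n)
        ffd = sr.FFDTransform.for_domain([0, 0, 0], [31, 31, 31], 10.0)
        ffd.coefficients = rng.normal(0, 0.5, ffd.coefficients.shape)
        t = sr.CombinedTransform(ffd=ffd)
        pts = rng.uniform(5, 26, (80, 3))
        zf = stack_n.sample(pts) + rng.normal(0, 0.1, (80, stack_n.d))
        return rng, model, t, pts, zf

    def test_matches_frozen_topology_finite_differences(self, gradient_problem):
        rng, model, t, pts, zf = gradient_problem
        cfg = EXACT_CFG
        topo = build_topology(zf, model.sample(t.apply(pts)), cfg)
        _, grad = alpha_mi_value_and_gradient(pts, zf, cfg, t, model, topology=topo)
        flat = t.ffd.coefficients.ravel()
        gflat = grad.ravel()

        def frozen_value():
            zm = model.sample(t.apply(pts))
            gf, gm, gfm = _gammas(zf, zm, cfg, topo)
            return _value_from_gammas(gf, gm, gfm, cfg, zf.shape[1])

        max_rel = 0.0
        for _ in range(20):
            v = rng.normal(size=flat.shape)
            v /= np.linalg.norm(v)
            eps = 1e-4
            flat += eps * v
            fp = frozen_value()
            flat -= 2 * eps * v
            fm = frozen_value()
            flat += eps * v
            fd = (fp - fm) / (2 * eps)
            max_rel = max(max_rel, abs(fd - gflat @ v) / max(abs(fd), 1e-12))
        assert max_rel < 1e-3

    def test_gradient_shape_matches_free_parameters(self, gradient_problem):
        _, model, t, pts, zf = gradient_problem
        _, grad = alpha_mi_value_and_gradient(pts, zf, EXACT_CFG, t, model)
        assert grad.shape == t.ffd.coefficients.shape

    def test_flat_constant_stacks_give_zero_gradient(self):
        vol = sr.Volume(np.full((32, 32, 32), 3.0))
        stack = sr.FeatureStack(channels=vol.data[None].copy(), names=["L"], scales=[],
                                spacing=np.ones(3), origin=np.zeros(3))
        model = MovingFeatureModel(stack)
        ffd = sr.FFDTransform.for_domain([0, 0, 0], [31, 31, 31], 12.0)
        t = sr.CombinedTransform(ffd=ffd)
        pts = np.random.default_rng(8).uniform(5, 26, (30, 3))
        zf = np.full((30, 1), 3.0)
        cfg = sr.AlphaMIConfig(k=3, alpha=0.99, ann_error_bound=0.0)
        _, grad = alpha_mi_value_and_gradient(pts, zf, cfg, t, model)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)
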