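import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import shapereg as sr


class TestGaussianDerivatives:
    def test_constant_volume_has_zero_derivatives(self):
        vol = sr.Volume(np.full((16, 16, 16), 7.0))
        g, H = sr.gaussian_derivatives(vol, 1.0)
        # zero up to the residual sum of the discrete derivative kernels
        np.testing.assert_allclose(g, 0.0, atol=1e-4)
        np.testing.assert_allclose(H, 0.0, atol=1e-4)

    def test_linear_ramp_gradient(self):
        x = np.arange(24, dtype=float)
        vol = sr.Volume(np.broadcast_to(x[:, None, None], (24, 24, 24)).copy())
        g, H = sr.gaussian_derivatives(vol, 1.0)
        interior = (slice(6, -6),) * 3
        np.testing.assert_allclose(g[interior + (0,)], 1.0, atol=1e-4)
        np.testing.assert_allclose(g[interior + (1,)], 0.0, atol=1e-4)
        np.testing.assert_allclose(H[interior], 0.0, atol=1e-4)

    def test_quadratic_hessian_matches_analytic_convolution(self):
        # d^2/dx^2 of G_sigma * x^2 is exactly 2 for any sigma
        x = np.arange(32, dtype=float)
        vol = sr.Volume(np.broadcast_to((x ** 2)[:, None, None], (32, 32, 32)).copy())
        _, H = sr.gaussian_derivatives(vol, 1.5)
        interior = (slice(10, -10),) * 3
        np.testing.assert_allclose(H[interior + (0, 0)], 2.0, rtol=1e-4)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            sr.gaussian_derivatives(sr.Volume(np.zeros((8, 8, 8))), 0.0)


class TestCartesianFeatures:
    @pytest.mark.parametrize(
        "g,H,expected",
        [
            ([1, 0, 0], np.zeros((3, 3)), [1, 0, 0, 0, 0, 0]),
            ([0, 0, 0], np.eye(3), [0, 0, 0, 3, 3, 3]),
            ([1, 1, 0], np.diag([2.0, 0, 0]), [2, 2, 4, 2, 4, 8]),
        ],
    )
    def test_closed_form_cases(self, g, H, expected):
        out = sr.cartesian_features(0.0, np.asarray(g, float), np.asarray(H, float))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_intensity_scaling_behaviour(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=3)
        H = rng.normal(size=(3, 3))
        H = H + H.T
        c = 3.7
        f1 = sr.cartesian_features(0.0, g, H)
        fc = sr.cartesian_features(0.0, c * g, c * H)
        np.testing.assert_allclose(fc[0], c ** 2 * f1[0], rtol=1e-12)  # g'g
        np.testing.assert_allclose(fc[3], c * f1[3], rtol=1e-12)  # tr H


class TestGradientOrientation:
    def test_pole_case_flags_phi(self):
        th, ph, deg = sr.gradient_orientation(np.array([0.0, 0.0, 2.0]))
        assert th == 0.0 and ph == 0.0 and deg

    def test_diagonal_vector(self):
        th, ph, deg = sr.gradient_orientation(np.array([1.0, 1.0, 1.0]))
        assert not deg
        np.testing.assert_allclose(th, np.arccos(1 / np.sqrt(3)), rtol=1e-12)
        np.testing.assert_allclose(ph, np.pi / 4, rtol=1e-12)

    def test_zero_gradient_sentinel(self):
        th, ph, deg = sr.gradient_orientation(np.zeros(3))
        assert (th, ph) == (0.0, 0.0) and deg

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        v=st.tuples(*[st.floats(-10, 10) for _ in range(3)]),
        c=st.floats(0.1, 100.0),
    )
    def test_invariant_to_positive_scaling(self, v, c):
        g = np.asarray(v)
        th1, ph1, d1 = sr.gradient_orientation(g)
        th2, ph2, d2 = sr.gradient_orientation(c * g)
        if not d1 and not d2:
            np.testing.assert_allclose([th1, ph1], [th2, ph2], atol=1e-9)


class TestFeatureStack:
    @pytest.mark.parametrize("scales,d", [((1.0, 2.0), 17), ((1.0,), 9)])
    def test_channel_count(self, textured_volume, scales, d):
        fs = sr.assemble_feature_stack(textured_volume, scales)
        assert fs.d == d
        assert len(fs.names) == d
        assert fs.names[0] == "L"

    def test_constant_volume_degenerate_orientations(self):
        vol = sr.Volume(np.full((32, 32, 32), 5.0))
        fs = sr.assemble_feature_stack(vol, (1.0,))
        np.testing.assert_allclose(fs.channels[1:7], 0.0, atol=1e-4)
        assert fs.degenerate.all()

    def test_channel_order_cartesian_then_orientation(self, textured_volume):
        fs = sr.assemble_feature_stack(textured_volume, (1.0, 2.0))
        assert fs.names == [
            "L",
            "gTg@1", "gTHg@1", "gTHHg@1", "trH@1", "trHH@1", "trHHH@1",
            "gTg@2", "gTHg@2", "gTHHg@2", "trH@2", "trHH@2", "trHHH@2",
            "theta@1", "phi@1", "theta@2", "phi@2",
        ]


class TestNormalization:
    def test_known_zscores_population_std(self):
        # channel with values 1, 2, 3 at three exact voxel centers
        data = np.zeros((8, 8, 8))
        data[1, 1, 1], data[2, 2, 2], data[3, 3, 3] = 1.0, 2.0, 3.0
        fs = sr.FeatureStack(channels=data[None], names=["L"], scales=[],
                             spacing=np.ones(3), origin=np.zeros(3))
        pts = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        out = sr.normalize_features(fs, pts)
        vals = out.sample(pts)[:, 0]
        np.testing.assert_allclose(vals, [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_idempotent_and_unit_moments(self, textured_volume):
        fs = sr.assemble_feature_stack(textured_volume, (1.0,))
        rng = np.random.default_rng(1)
        pts = rng.uniform(4, 27, (500, 3))
        once = sr.normalize_features(fs, pts)
        vals = once.sample(pts)
        np.testing.assert_allclose(vals.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(vals.var(axis=0), 1.0, atol=1e-6)
        twice = sr.normalize_features(once, pts)
        np.testing.assert_allclose(twice.channels, once.channels, atol=1e-12)

    def test_constant_channel_dropped_with_warning(self, textured_volume):
        fs = sr.assemble_feature_stack(textured_volume, (1.0,))
        fs.channels[4][...] = 3.14  # make one channel constant
        pts = np.random.default_rng(2).uniform(4, 27, (200, 3))
        with pytest.warns(UserWarning, match="constant feature channel"):
            out = sr.normalize_features(fs, pts)
        assert out.d == fs.d - 1
        assert fs.names[4] not in out.names

    def test_same_normalization_applies_to_moving_stack(self, textured_volume):
        fs = sr.assemble_feature_stack(textured_volume, (1.0,))
        pts = np.random.default_rng(3).uniform(4, 27, (300, 3))
        fn = sr.normalize_features(fs, pts)
        mn = sr.apply_normalization(fs, fn.normalization, fn.names)
        np.testing.assert_allclose(mn.channels, fn.channels, atol=1e-12)
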