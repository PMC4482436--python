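import numpy as np
import pytest

import shapereg as sr


@pytest.fixture(scope="session")
def phantom48():
    """Small textured multi-chamber phantom with labels (48^3, 1 mm)."""
    spec = sr.PhantomSpec(size=(48, 48, 48), seed=0)
    vol, lab = sr.make_phantom(spec)
    return vol, lab


@pytest.fixture(scope="session")
def case48():
    """Registration case with a known 6 mm B-spline warp on a 48^3 phantom."""
    spec = sr.PhantomSpec(size=(48, 48, 48), seed=7)
    return sr.make_case(spec, warp_magnitude=6.0, warp_grid_spacing=20.0, seed=7)


@pytest.fixture(scope="session")
def textured_volume():
    """Smooth random texture volume (32^3) whose gradients are informative."""
    rng = np.random.default_rng(42)
    from scipy import ndimage

    data = ndimage.gaussian_filter(rng.normal(0, 1, (32, 32, 32)), 2.0) * 40 + 100
    return sr.Volume(data)


@pytest.fixture
def random_ffd():
    rng = np.random.default_rng(3)
    ffd = sr.FFDTransform.for_domain([0, 0, 0], [47, 47, 47], 12.0)
    ffd.coefficients = rng.normal(0, 1.0, ffd.coefficients.shape)
    return ffd
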