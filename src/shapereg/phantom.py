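"""Synthetic multi-chamber phantoms with known ground-truth deformations.

The phantom emulates a contrast-enhanced cardiac CT at desk scale: up to
six disjoint structures (AO, LV, LVM, LA, RV, RA roles) built from
ellipsoids, with the left/right ventricles and atria sharing flat chamber
interfaces and a myocardium-like shell around the LV.  Each structure has
a distinct mean intensity; smooth random texture makes gradient features
informative everywhere.

``make_case`` draws a random B-spline deformation (the same transform
family the registration estimates, on a coarser lattice), produces the
fixed image by warping a base volume through it and treats the unwarped
base as the moving image, so the ground-truth fixed-to-moving mapping is
the drawn transform itself: M(T_true(x)) = F(x) and surface landmarks obey
p_m = T_true(p_f) exactly.  Independent Gaussian noise is added to the
fixed and moving images after warping.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .penalty import ShapePointPairs
from .transforms import CombinedTransform, FFDTransform
from .volume import CARDIAC_LABELS, LabelVolume, Volume, resample

#: structure order used for intensity levels
STRUCTURE_ORDER = ("AO", "LV", "LVM", "LA", "RV", "RA")
DEFAULT_LEVELS = (210.0, 200.0, 120.0, 190.0, 185.0, 180.0)
BACKGROUND_LEVEL = 40.0


@dataclass
class PhantomSpec:
    size: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    n_structures: int = 6
    intensity_levels: tuple = DEFAULT_LEVELS
    background_level: float = BACKGROUND_LEVEL
    texture_sigma: float = 2.0  # voxels
    texture_amplitude: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_structures <= 6:
            raise ValueError("n_structures must be in 1..6")
        if any(s < 32 for s in self.size):
            raise ValueError("phantom size must be >= 32 per axis")
        if len(self.intensity_levels) < self.n_structures:
            raise ValueError("need an intensity level per structure")


def low_contrast_spec(**overrides) -> PhantomSpec:
    """Spec with ambiguous, flat-intensity boundary regions.

    The atria match their ventricles in intensity (LA = LV, RA = RV) and
    the blood-pool texture is nearly flat, so the atrium/ventricle
    interfaces are invisible to any intensity-driven metric while the
    label maps still separate them -- the regime where shape information
    should help.
    """
    overrides.setdefault("intensity_levels", (210.0, 200.0, 120.0, 200.0, 185.0, 185.0))
    overrides.setdefault("texture_amplitude", 2.0)
    return PhantomSpec(**overrides)


def _ellipsoid(grid, center_frac, radii_frac, extent):
    x, y, z = grid
    c = np.asarray(center_frac) * extent
    r = np.asarray(radii_frac) * extent
    return ((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2 <= 1.0


def _structure_masks(spec: PhantomSpec):
    """Disjoint boolean masks in STRUCTURE_ORDER (first n_structures)."""
    shape = tuple(int(s) for s in spec.size)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    extent = (np.asarray(shape) - 1) * spacing
    ax = [np.arange(n) * sp for n, sp in zip(shape, spacing)]
    grid = np.meshgrid(*ax, indexing="ij")
    z = grid[2]
    z_left = 0.56 * extent[2]  # LV | LA interface plane
    z_right = 0.58 * extent[2]  # RV | RA interface plane

    lv_ell = _ellipsoid(grid, (0.38, 0.42, 0.44), (0.15, 0.14, 0.22), extent)
    lv = lv_ell & (z <= z_left)
    lvm = (_ellipsoid(grid, (0.38, 0.42, 0.44), (0.21, 0.20, 0.28), extent)
           & ~lv_ell & (z <= z_left))
    la = _ellipsoid(grid, (0.40, 0.42, 0.64), (0.11, 0.11, 0.16), extent) & (z > z_left)
    rv = _ellipsoid(grid, (0.72, 0.42, 0.42), (0.12, 0.13, 0.20), extent) & (z <= z_right)
    ra = _ellipsoid(grid, (0.73, 0.43, 0.66), (0.10, 0.11, 0.14), extent) & (z > z_right)
    ao = _ellipsoid(grid, (0.55, 0.68, 0.70), (0.06, 0.06, 0.14), extent)
    masks = {"AO": ao, "LV": lv, "LVM": lvm, "LA": la, "RV": rv, "RA": ra}
    out = []
    for name in STRUCTURE_ORDER[: spec.n_structures]:
        m = masks[name]
        if not m.any():
            raise ValueError(f"structure {name} is empty; spec does not fit the domain")
        out.append((name, m))
    total = np.zeros(shape, dtype=np.int32)
    for _, m in out:
        total += m
    if total.max() > 1:
        raise ValueError("structures overlap; phantom spec invalid")
    return out


def make_phantom(spec: PhantomSpec, include_noise: bool = True):
    """Build the phantom volume and its label map (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    masks = _structure_masks(spec)
    shape = tuple(int(s) for s in spec.size)
    data = np.full(shape, float(spec.background_level))
    labels = np.zeros(shape, dtype=np.int32)
    for (name, m), level in zip(masks, spec.intensity_levels):
        data[m] = level
        labels[m] = CARDIAC_LABELS[name]
    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), spec.texture_sigma)
        tex /= max(tex.std(), 1e-12)
        data = data + spec.texture_amplitude * tex
    if include_noise and spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(shape)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    vol = Volume(data, spacing, np.zeros(3))
    lab = LabelVolume(labels, spacing.copy(), np.zeros(3))
    return vol, lab


@dataclass
class PhantomCase:
    fixed: Volume
    fixed_labels: LabelVolume
    moving: Volume
    moving_labels: LabelVolume
    true_transform: CombinedTransform
    true_pairs: ShapePointPairs
    spec: PhantomSpec = field(default=None)


def deformation_is_folded(ffd: FFDTransform, vol: Volume, stride: int = 2) -> bool:
    """True if det(I + du/dx) <= 0 anywhere on a strided voxel grid."""
    pts = vol.grid_points(step=stride)
    J = ffd.spatial_jacobian(pts)
    det = np.linalg.det(np.eye(3)[None] + J)
    return bool(np.any(det <= 0))


def make_case(spec: PhantomSpec, warp_magnitude: float = 8.0,
              warp_grid_spacing: float = 24.0, seed: int | None = None,
              decimation_rate: float = 0.96, landmark_labels=None) -> PhantomCase:
    """Phantom registration case with known ground truth.

    Control-point displacements are drawn uniformly in +-warp_magnitude on
    a lattice of ``warp_grid_spacing`` (mm); draws producing a folded
    deformation are rejected (up to 10 attempts).  Landmarks are decimated
    fixed-surface nodes with p_m = T_true(p_f) exactly.
    """
    if warp_magnitude > warp_grid_spacing / 2.0:
        raise ValueError("warp magnitude must stay below half the warp grid spacing")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    base, base_labels = make_phantom(spec, include_noise=False)
    lo, hi = base.domain()

    template = FFDTransform.for_domain(lo, hi, warp_grid_spacing)
    for attempt in range(10):
        coeffs = rng.uniform(-warp_magnitude, warp_magnitude, template.coefficients.shape)
        ffd = FFDTransform(template.grid_origin, template.grid_spacing, coeffs)
        if warp_magnitude == 0 or not deformation_is_folded(ffd, base):
            break
    else:
        raise RuntimeError("could not draw a fold-free deformation in 10 attempts")
    t_true = CombinedTransform(ffd=ffd)

    fixed = resample(base, t_true, base)
    fixed_labels = resample(base_labels, t_true, base_labels)
    moving = Volume(base.data.copy(), base.spacing.copy(), base.origin.copy())
    moving_labels = LabelVolume(base_labels.data.copy(), base_labels.spacing.copy(),
                                base_labels.origin.copy(), labels=dict(base_labels.labels))
    if spec.noise_sd > 0:
        fixed.data = fixed.data + spec.noise_sd * rng.standard_normal(fixed.data.shape)
        moving.data = moving.data + spec.noise_sd * rng.standard_normal(moving.data.shape)

    from .shape import extract_shape_points

    p_f, codes = extract_shape_points(fixed_labels, labels=landmark_labels,
                                      rate=decimation_rate)
    pairs = ShapePointPairs(p_f=p_f, p_m=t_true.apply(p_f), structure=codes)
    return PhantomCase(fixed=fixed, fixed_labels=fixed_labels, moving=moving,
                       moving_labels=moving_labels, true_transform=t_true,
                       true_pairs=pairs, spec=spec)
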