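"""Shape-regularized multifeature nonrigid registration pipeline.

The cost minimized over the FFD coefficients mu is

    C(mu) = -alphaMI(mu) + omega * C_P(mu)

where alphaMI is the kNN-graph multifeature mutual information and C_P the
mean shape-point residual; omega in [0.01, 0.1] balances the two (omega=0
disables the shape term).  Optimization is a decaying-gain stochastic
gradient descent, step size a / (A + k + 1)^tau, over a smoothing-only
multiresolution pyramid (no downsampling): at each level both images are
Gaussian-smoothed, feature stacks are rebuilt, and the B-spline control
grid is refined.  Fresh random coordinate samples are drawn every
iteration, so the metric and its gradient are stochastic.

Full-scale defaults follow the cardiac-CT protocol (five levels, smoothing
sigmas 16/8/4/2/1 voxels, grid spacings 80/40/20/10/5 mm, A=50, tau=0.6,
1000 iterations per level, 5000 samples, k=5, alpha=0.99, omega=0.05);
desk-scale problems use reduced schedules via the same config.
"""
from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .alpha_mi import (
    AlphaMIConfig,
    MetricUndefinedError,
    MovingFeatureModel,
    alpha_mi_value_and_gradient,
)
from .features import apply_normalization, assemble_feature_stack, normalize_features
from .penalty import ShapePointPairs, penalty, penalty_gradient
from .transforms import AffineTransform, CombinedTransform, FFDTransform
from .volume import LabelVolume, Volume, gaussian_smooth


@dataclass
class RegistrationConfig:
    """All scalar knobs of the pipeline; defaults are the full-scale protocol."""

    omega: float = 0.05
    num_samples: int = 5000
    iterations: int = 1000
    pyramid_sigmas: tuple = (16.0, 8.0, 4.0, 2.0, 1.0)  # voxels
    grid_spacings: tuple = (80.0, 40.0, 20.0, 10.0, 5.0)  # mm
    A: float = 50.0
    tau: float = 0.6
    a: float | str = "auto"  # gain numerator; "auto" calibrates per level
    step0_mm: float = 0.5  # first-step max control-point update under "auto"
    alpha_mi: AlphaMIConfig = field(default_factory=AlphaMIConfig)
    feature_scales: tuple = (1.0, 2.0)
    intensity_only: bool = False  # single-feature conventional baseline
    seed: int = 0
    affine_init: str = "mi"  # "mi" (intensity mutual information) or "none"
    mi_bins: int = 32
    decimation_rate: float = 0.96
    shape_labels: tuple | None = None  # default: all labels except LV
    compose_at_affine: bool = True
    sample_margin_vox: float = 2.0
    binary_sigmas: tuple = (4.0, 2.0, 1.0)
    binary_grid_spacings: tuple = (32.0, 16.0, 8.0)
    binary_iterations: int = 60
    binary_num_samples: int = 3000

    def __post_init__(self):
        if self.omega != 0.0 and not (0.01 <= self.omega <= 0.1):
            raise ValueError("omega must be 0 (disabled) or within [0.01, 0.1]")
        if len(self.pyramid_sigmas) != len(self.grid_spacings):
            raise ValueError("pyramid_sigmas and grid_spacings must have equal length")
        if self.affine_init not in ("mi", "none"):
            raise ValueError("affine_init must be 'mi' or 'none'")

    @property
    def levels(self) -> int:
        return len(self.pyramid_sigmas)


@dataclass
class RegistrationResult:
    transform: CombinedTransform
    cost_traces: list  # one array per level
    final_alpha_mi: float
    final_penalty: float
    config: RegistrationConfig
    log: list
    shape_pairs: ShapePointPairs | None = None


def asgd_gain(k: int, A: float, tau: float, a: float) -> float:
    """Decaying gain a / (A + k + 1)^tau of the stochastic descent."""
    return a / (A + k + 1.0) ** tau


def asgd_step(mu: np.ndarray, gradient: np.ndarray, k: int,
              A: float, tau: float, a: float) -> np.ndarray:
    """mu_{k+1} = mu_k - a/(A+k+1)^tau * gradient; skips non-finite gradients."""
    gradient = np.asarray(gradient, dtype=np.float64)
    if not np.all(np.isfinite(gradient)):
        warnings.warn(f"non-finite gradient at iteration {k}; step skipped")
        return np.asarray(mu, dtype=np.float64).copy()
    return np.asarray(mu, dtype=np.float64) - asgd_gain(k, A, tau, a) * gradient


def cost(transform: CombinedTransform, fixed_stack, moving: MovingFeatureModel,
         pairs: ShapePointPairs | None, cfg: RegistrationConfig, rng: np.random.Generator,
         domain_lo: np.ndarray, domain_hi: np.ndarray):
    """One stochastic evaluation of C = -alphaMI + omega * C_P and gradient.

    Draws a fresh uniform sample of ``cfg.num_samples`` fixed-domain points.
    Returns (value, gradient, alpha_mi_value, penalty_value).
    """
    pts = domain_lo + rng.random((cfg.num_samples, 3)) * (domain_hi - domain_lo)
    zf = fixed_stack.sample(pts)
    mi, g_mi = alpha_mi_value_and_gradient(pts, zf, cfg.alpha_mi, transform, moving)
    value = -mi
    grad = -g_mi
    pen_value = 0.0
    if cfg.omega > 0.0:
        if pairs is None or len(pairs) == 0:
            raise ValueError("omega > 0 requires shape point pairs")
        pen = penalty(pairs, transform)
        pen_value = pen.value
        value = value + cfg.omega * pen_value
        grad = grad + cfg.omega * penalty_gradient(pairs, transform)
    return value, grad, mi, pen_value


def _sitk_image(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0).astype(np.float64)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def affine_mi_initialize(fixed: Volume, moving: Volume, bins: int = 32) -> AffineTransform:
    """Affine pre-alignment by histogram mutual information of intensities.

    Dense (non-stochastic) Mattes MI so the result is deterministic.
    Falls back to identity with a warning if the optimizer fails.
    """
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=100,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    fimg = _sitk_image(fixed)
    mimg = _sitk_image(moving)
    init = sitk.CenteredTransformInitializer(
        fimg, mimg, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg.SetInitialTransform(init, inPlace=False)
    try:
        out = reg.Execute(fimg, mimg)
    except RuntimeError as exc:
        warnings.warn(f"affine MI initialization failed ({exc}); using identity")
        return AffineTransform()
    aff = sitk.AffineTransform(out.GetNthTransform(0) if hasattr(out, "GetNthTransform") else out)
    matrix = np.asarray(aff.GetMatrix()).reshape(3, 3)
    return AffineTransform(matrix=matrix,
                           translation=np.asarray(aff.GetTranslation()),
                           center=np.asarray(aff.GetCenter()))


def _level_ffd(prev: FFDTransform | None, lo, hi, spacing: float) -> FFDTransform:
    """FFD lattice for a pyramid level, carrying over the deformation.

    Exact dyadic refinement when the spacing halves; otherwise the new
    coefficients interpolate the previous displacement at the node sites
    (approximate, warned).
    """
    if prev is None:
        return FFDTransform.for_domain(lo, hi, spacing)
    ratio = prev.grid_spacing[0] / spacing
    if abs(ratio - 2.0) < 1e-9:
        return prev.refine()
    if abs(ratio - 1.0) < 1e-9:
        return prev
    warnings.warn("non-dyadic grid schedule: carrying deformation over by node sampling")
    new = FFDTransform.for_domain(lo, hi, spacing)
    node_idx = np.stack(np.meshgrid(*[np.arange(n) for n in new.n_nodes], indexing="ij"),
                        axis=-1).reshape(-1, 3)
    node_pts = new.grid_origin + node_idx * new.grid_spacing
    new.coefficients = prev.displacement(node_pts).reshape(*new.n_nodes, 3)
    return new


def register(fixed: Volume, moving: Volume,
             fixed_seg: LabelVolume | None = None,
             moving_seg: LabelVolume | None = None,
             cfg: RegistrationConfig | None = None,
             pairs: ShapePointPairs | None = None) -> RegistrationResult:
    """Run the full pipeline; returns the fixed->moving CombinedTransform.

    Stages: (1) affine initialization by intensity MI; (2) when omega > 0,
    shape-point extraction from the fixed segmentation and propagation to
    the moving image via kappa-driven binary registration (skipped if
    ``pairs`` is supplied); (3) per pyramid level, Gaussian smoothing of
    both images (no downsampling), feature-stack construction and
    normalization, and ``cfg.iterations`` stochastic gradient steps on the
    combined cost.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or RegistrationConfig()
    rng = np.random.default_rng(cfg.seed)
    log: list[str] = []
    t0 = time.time()

    if cfg.affine_init == "mi":
        affine = affine_mi_initialize(fixed, moving, cfg.mi_bins)
        log.append(f"affine MI init: translation {np.round(affine.translation, 3)}")
    else:
        affine = AffineTransform()
        log.append("affine init skipped")

    if cfg.omega > 0.0 and pairs is None:
        if fixed_seg is None or moving_seg is None:
            raise ValueError("omega > 0 requires segmentations (or explicit pairs)")
        from .shape import build_shape_pairs

        pairs = build_shape_pairs(
            fixed_seg, moving_seg,
            labels=list(cfg.shape_labels) if cfg.shape_labels else None,
            rate=cfg.decimation_rate, seed=cfg.seed,
            sigmas=cfg.binary_sigmas, grid_spacings=cfg.binary_grid_spacings,
            iterations=cfg.binary_iterations, n_samples=cfg.binary_num_samples)
        log.append(f"shape correspondence: {len(pairs)} point pairs")

    lo, hi = fixed.domain()
    margin = cfg.sample_margin_vox * fixed.spacing
    slo, shi = lo + margin, hi - margin

    ffd: FFDTransform | None = None
    traces = []
    mi_val = np.nan
    pen_val = 0.0
    for level in range(cfg.levels):
        sigma = cfg.pyramid_sigmas[level]
        ffd = _level_ffd(ffd, lo, hi, cfg.grid_spacings[level])
        transform = CombinedTransform(affine=affine, ffd=ffd,
                                      compose_at_affine=cfg.compose_at_affine)

        fsm = gaussian_smooth(fixed, sigma)
        msm = gaussian_smooth(moving, sigma)
        fstack_raw = assemble_feature_stack(fsm, cfg.feature_scales)
        mstack_raw = assemble_feature_stack(msm, cfg.feature_scales)
        if cfg.intensity_only:
            for stk in (fstack_raw, mstack_raw):
                stk.channels = stk.channels[:1]
                stk.names = stk.names[:1]
        norm_pts = slo + rng.random((min(cfg.num_samples, 4000), 3)) * (shi - slo)
        fstack = normalize_features(fstack_raw, norm_pts)
        mstack = apply_normalization(mstack_raw, fstack.normalization, fstack.names)
        moving_model = MovingFeatureModel(mstack)
        log.append(f"level {level}: sigma={sigma}, grid={cfg.grid_spacings[level]}mm, "
                   f"d={fstack.d}, nodes={ffd.n_nodes}")

        a_eff = cfg.a
        trace = np.empty(cfg.iterations)
        for k in range(cfg.iterations):
            try:
                value, grad, mi_val, pen_val = cost(
                    transform, fstack, moving_model, pairs, cfg, rng, slo, shi)
            except MetricUndefinedError as exc:
                warnings.warn(f"level {level} iteration {k}: {exc}; stopping level")
                trace = trace[:k]
                break
            if a_eff == "auto":
                gmax = float(np.abs(grad).max())
                a_eff = 0.0 if gmax == 0 else cfg.step0_mm * (cfg.A + 1.0) ** cfg.tau / gmax
                log.append(f"level {level}: auto gain a={a_eff:.4g}")
            trace[k] = value
            mu = asgd_step(ffd.coefficients.ravel(), grad.ravel(), k, cfg.A, cfg.tau, a_eff)
            ffd.coefficients = mu.reshape(ffd.coefficients.shape)
        traces.append(trace)

    log.append(f"total time {time.time() - t0:.1f}s")
    final = CombinedTransform(affine=affine, ffd=ffd, compose_at_affine=cfg.compose_at_affine)
    return RegistrationResult(transform=final, cost_traces=traces,
                              final_alpha_mi=float(mi_val), final_penalty=float(pen_val),
                              config=cfg, log=log, shape_pairs=pairs)


def reduced_config(**overrides) -> RegistrationConfig:
    """A desk-scale schedule for 64^3-ish problems: 2 levels, 200 iterations,
    2000 samples, 32/16 mm grids.  Keyword overrides are applied on top."""
    base = RegistrationConfig(
        num_samples=2000, iterations=200,
        pyramid_sigmas=(2.0, 1.0), grid_spacings=(32.0, 16.0),
        binary_iterations=40, binary_num_samples=2000)
    return replace(base, **overrides)
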