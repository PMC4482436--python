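"""kNN-graph alpha-mutual-information over multifeature samples.

For N sample points with fixed-image feature vectors z^f, moving-image
feature vectors z^m (taken at the transformed points) and their
concatenation z^fm, three k-nearest-neighbour graphs supply per-sample
total neighbour distances Gamma^f_i, Gamma^m_i, Gamma^fm_i.  The metric is

    alpha-MI = 1/(alpha-1) * log[ 1/N^alpha * sum_i
               (Gamma^fm_i / (Gamma^f_i * Gamma^m_i))^(2*gamma) ]

with gamma = d * (1 - alpha), 0 < alpha < 1, and d the per-image feature
dimension.  The estimator is implemented literally with the product
denominator; the sqrt-product variant used by a related published
estimator is available via ``denominator="sqrt_product"``.

The analytic gradient with respect to FFD coefficients holds the graph
topology fixed (neighbour indices treated as locally constant) and chains
through the moving-stack interpolation and the B-spline parameter
Jacobian.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._bspline import SplineField
from .features import FeatureStack
from .transforms import CombinedTransform


class MetricUndefinedError(RuntimeError):
    """Raised when too few valid samples remain to build the kNN graphs."""


@dataclass
class AlphaMIConfig:
    k: int = 5
    alpha: float = 0.99
    denominator: str = "product"  # or "sqrt_product"
    epsilon_dist: float = 1e-10
    ann_error_bound: float = 10.0  # approximate-search slack (kd-tree eps)
    bucket_size: int = 50

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.denominator not in ("product", "sqrt_product"):
            raise ValueError(f"unknown denominator {self.denominator!r}")

    def gamma(self, d: int) -> float:
        return d * (1.0 - self.alpha)


@dataclass
class FeatureSampleSet:
    """Aligned fixed/moving feature samples at N fixed-domain points."""

    points: np.ndarray  # (N, 3) mm, fixed domain
    zf: np.ndarray  # (N, d)
    zm: np.ndarray  # (N, d)
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.zf = np.atleast_2d(np.asarray(self.zf, dtype=np.float64))
        self.zm = np.atleast_2d(np.asarray(self.zm, dtype=np.float64))
        if self.zf.shape != self.zm.shape:
            raise ValueError("zf and zm must have identical shape")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.zf), dtype=bool)


def knn_total_distance(vectors: np.ndarray, i: int, k: int) -> float:
    """Sum of Euclidean distances from row ``i`` to its k nearest other rows."""
    X = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if k >= len(X):
        raise ValueError(f"k={k} must be smaller than the number of rows {len(X)}")
    d = np.linalg.norm(X - X[i], axis=1)
    d = np.delete(d, i)
    return float(np.sort(d)[:k].sum())


def knn_graph(X: np.ndarray, k: int, eps: float = 0.0, leafsize: int = 50) -> np.ndarray:
    """Neighbour index array (N, k) excluding self, kd-tree accelerated.

    ``eps`` is the approximate-search error bound (0 = exact).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n = len(X)
    if k >= n:
        raise MetricUndefinedError(f"need more than k={k} samples, have {n}")
    tree = cKDTree(X, leafsize=max(1, leafsize))
    _, idx = tree.query(X, k=k + 1, eps=eps)
    rows = np.arange(n)[:, None]
    self_hit = idx == rows
    # keep k columns: drop self if listed, else drop the farthest
    keep = np.empty((n, k), dtype=np.int64)
    has_self = self_hit.any(axis=1)
    for r in np.nonzero(has_self)[0]:
        keep[r] = idx[r][~self_hit[r]][:k]
    keep[~has_self] = idx[~has_self, :k]
    return keep


def graph_total_distances(X: np.ndarray, nbrs: np.ndarray) -> np.ndarray:
    """Gamma_i = sum_p ||X_i - X_{nbrs[i,p]}|| for a fixed topology."""
    diff = X[:, None, :] - X[nbrs]
    return np.linalg.norm(diff, axis=2).sum(axis=1)


def build_topology(zf, zm, cfg: AlphaMIConfig):
    """Neighbour lists for the three graphs (fixed, moving, joint)."""
    zfm = np.concatenate([zf, zm], axis=1)
    return (
        knn_graph(zf, cfg.k, cfg.ann_error_bound, cfg.bucket_size),
        knn_graph(zm, cfg.k, cfg.ann_error_bound, cfg.bucket_size),
        knn_graph(zfm, cfg.k, cfg.ann_error_bound, cfg.bucket_size),
    )


def _gammas(zf, zm, cfg, topology):
    zfm = np.concatenate([zf, zm], axis=1)
    nf, nm, nfm = topology
    eps = cfg.epsilon_dist
    gf = np.maximum(graph_total_distances(zf, nf), eps)
    gm = np.maximum(graph_total_distances(zm, nm), eps)
    gfm = np.maximum(graph_total_distances(zfm, nfm), eps)
    return gf, gm, gfm


def _value_from_gammas(gf, gm, gfm, cfg, d):
    n = len(gf)
    denom = gf * gm if cfg.denominator == "product" else np.sqrt(gf * gm)
    ratio = gfm / denom
    two_gamma = 2.0 * cfg.gamma(d)
    s = float(np.sum(ratio ** two_gamma))
    s = max(s, cfg.epsilon_dist)
    return (np.log(s) - cfg.alpha * np.log(n)) / (cfg.alpha - 1.0)


def alpha_mi(samples: FeatureSampleSet, cfg: AlphaMIConfig, topology=None) -> float:
    """alpha-MI of a sample set; higher means better feature agreement.

    With ``topology`` given (three (N, k) neighbour index arrays over the
    valid rows) the graphs are frozen — used for finite-difference checks
    of the analytic gradient.
    """
    m = samples.valid_mask
    zf, zm = samples.zf[m], samples.zm[m]
    if len(zf) < cfg.k + 1:
        raise MetricUndefinedError(
            f"alpha-MI needs at least k+1={cfg.k + 1} valid samples, have {len(zf)}"
        )
    if topology is None:
        topology = build_topology(zf, zm, cfg)
    gf, gm, gfm = _gammas(zf, zm, cfg, topology)
    return float(_value_from_gammas(gf, gm, gfm, cfg, zf.shape[1]))


class MovingFeatureModel:
    """Differentiable sampler of a moving-image feature stack.

    Channels are interpolated with cubic B-splines so values and spatial
    gradients are mutually consistent (finite differences of the sampled
    values match the analytic gradients).
    """

    def __init__(self, stack: FeatureStack):
        self.stack = stack
        self.field = SplineField(stack.channels)
        self.spacing = stack.spacing
        self.origin = stack.origin
        self.shape = np.asarray(stack.channels.shape[1:])

    @property
    def d(self) -> int:
        return self.stack.d

    def inside(self, world_points: np.ndarray) -> np.ndarray:
        vox = (np.atleast_2d(world_points) - self.origin) / self.spacing
        return np.all((vox >= 0) & (vox <= self.shape - 1), axis=1)

    def sample(self, world_points: np.ndarray) -> np.ndarray:
        vox = (np.atleast_2d(world_points) - self.origin) / self.spacing
        return self.field.evaluate(vox).T  # (N, d)

    def sample_with_gradient(self, world_points: np.ndarray):
        """Values (N, d) and spatial gradients (N, d, 3) in 1/mm."""
        vox = (np.atleast_2d(world_points) - self.origin) / self.spacing
        val, grad = self.field.evaluate_with_gradient(vox)
        grad = grad / self.spacing[None, None, :]
        return val.T, np.transpose(grad, (1, 0, 2))


def alpha_mi_value_and_gradient(
    points: np.ndarray,
    zf: np.ndarray,
    cfg: AlphaMIConfig,
    transform: CombinedTransform,
    moving: MovingFeatureModel,
    topology=None,
):
    """alpha-MI and its gradient over the FFD coefficients.

    ``points`` are fixed-domain sample coordinates (mm) with aligned
    fixed-feature rows ``zf``.  Moving features are sampled at T(points);
    samples mapping outside the moving domain or outside the FFD support
    are dropped from all three graphs.  Returns (value, grad) with grad
    shaped like ``transform.ffd.coefficients``.
    """
    if transform.ffd is None:
        raise ValueError("transform must carry an FFD to differentiate")
    points = np.atleast_2d(points)
    mapped = transform.apply(points)
    eval_pts = transform.ffd_eval_points(points)
    jac_idx, jac_w, support = transform.ffd.jacobian_struct(eval_pts)
    valid = moving.inside(mapped) & support
    if valid.sum() < cfg.k + 1:
        raise MetricUndefinedError("too few valid samples for alpha-MI gradient")

    pts_v = mapped[valid]
    zf_v = np.asarray(zf, dtype=np.float64)[valid]
    zm_v, dzm = moving.sample_with_gradient(pts_v)  # (n, d), (n, d, 3)
    if topology is None:
        topology = build_topology(zf_v, zm_v, cfg)
    nf, nm, nfm = topology
    gf, gm, gfm = _gammas(zf_v, zm_v, cfg, topology)
    d = zf_v.shape[1]
    value = _value_from_gammas(gf, gm, gfm, cfg, d)

    two_gamma = 2.0 * cfg.gamma(d)
    denom = gf * gm if cfg.denominator == "product" else np.sqrt(gf * gm)
    ratio = gfm / denom
    s = max(float(np.sum(ratio ** two_gamma)), cfg.epsilon_dist)
    w_i = (two_gamma / ((cfg.alpha - 1.0) * s)) * ratio ** two_gamma  # (n,)
    gm_factor = 1.0 if cfg.denominator == "product" else 0.5

    eps = cfg.epsilon_dist
    A = np.zeros_like(zm_v)  # per-sample d-vectors accumulating d(Gamma)/d(zm)

    # moving graph: contributes -w_i * dlog Gamma^m_i (scaled by gm_factor)
    diff_m = zm_v[:, None, :] - zm_v[nm]  # (n, k, d)
    norm_m = np.maximum(np.linalg.norm(diff_m, axis=2), eps)
    unit_m = diff_m / norm_m[:, :, None]
    coef_m = (-gm_factor) * w_i / gm  # (n,)
    contrib = coef_m[:, None, None] * unit_m  # (n, k, d)
    A += contrib.sum(axis=1)
    np.add.at(A, nm.ravel(), -contrib.reshape(-1, zm_v.shape[1]))

    # joint graph: contributes +w_i * dlog Gamma^fm_i; only the zm half of
    # the joint difference vector depends on mu
    diff_f = zf_v[:, None, :] - zf_v[nfm]
    diff_jm = zm_v[:, None, :] - zm_v[nfm]
    norm_fm = np.maximum(
        np.sqrt((diff_f ** 2).sum(axis=2) + (diff_jm ** 2).sum(axis=2)), eps
    )
    unit_jm = diff_jm / norm_fm[:, :, None]
    coef_fm = w_i / gfm
    contrib = coef_fm[:, None, None] * unit_jm
    A += contrib.sum(axis=1)
    np.add.at(A, nfm.ravel(), -contrib.reshape(-1, zm_v.shape[1]))

    # chain through moving-feature spatial gradients: V_j = dzm_j' A_j
    V = np.einsum("ndc,nd->nc", dzm, A)  # (n, 3)

    grad = np.zeros(transform.ffd.n_parameters)
    idx_v = jac_idx[valid]
    w_v = jac_w[valid]
    flat = (idx_v * 3)[:, :, None] + np.arange(3)[None, None, :]  # (n, 64, 3)
    np.add.at(grad, flat.ravel(), (w_v[:, :, None] * V[:, None, :]).ravel())
    return value, grad.reshape(transform.ffd.coefficients.shape)


def alpha_mi_gradient(samples: FeatureSampleSet, cfg: AlphaMIConfig,
                      transform: CombinedTransform, moving: MovingFeatureModel):
    """Gradient-only convenience wrapper over sample points."""
    _, grad = alpha_mi_value_and_gradient(samples.points, samples.zf, cfg, transform, moving)
    return grad
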