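"""Shape-point consistency penalty and its analytic gradient.

Given corresponding shape points {(p_f_i, p_m_i)} on the fixed and moving
images, the penalty is the mean Euclidean residual

    C_P = (1/N) * sum_i || p_m_i - T_mu(p_f_i) ||

and its derivative with respect to the FFD coefficients chains the unit
residual direction through the B-spline parameter Jacobian:

    dC_P/dmu = -(1/N) * sum_i (p_m_i - T(p_f_i)) / ||...|| * dT/dmu(p_f_i)

Pairs whose residual is below 1e-9 mm sit at the cone point of the norm
and contribute zero gradient (a subgradient choice).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import CombinedTransform

RESIDUAL_EPS = 1e-9


@dataclass
class ShapePointPairs:
    """Corresponding landmark sets; row i pairs p_f[i] with p_m[i] (mm)."""

    p_f: np.ndarray
    p_m: np.ndarray
    structure: np.ndarray | None = None  # optional per-point label code

    def __post_init__(self):
        self.p_f = np.atleast_2d(np.asarray(self.p_f, dtype=np.float64))
        self.p_m = np.atleast_2d(np.asarray(self.p_m, dtype=np.float64))
        if self.p_f.shape != self.p_m.shape:
            raise ValueError("p_f and p_m must have equal shapes")

    def __len__(self) -> int:
        return len(self.p_f)


@dataclass
class PenaltyResult:
    value: float
    per_point_residuals: np.ndarray
    gradient: np.ndarray | None = None


def penalty(pairs: ShapePointPairs, t: CombinedTransform) -> PenaltyResult:
    """Mean distance between p_m and T(p_f); >= 0, zero iff all matched."""
    if len(pairs) == 0:
        raise ValueError("penalty requires at least one shape point pair")
    res = np.linalg.norm(pairs.p_m - t.apply(pairs.p_f), axis=1)
    return PenaltyResult(value=float(res.mean()), per_point_residuals=res)


def penalty_gradient(pairs: ShapePointPairs, t: CombinedTransform) -> np.ndarray:
    """dC_P/dmu, shaped like the FFD coefficient lattice.

    Only lattice nodes whose cubic support covers some p_f receive nonzero
    entries; residuals below ``RESIDUAL_EPS`` are skipped.
    """
    if t.ffd is None:
        raise ValueError("transform must carry an FFD to differentiate")
    if len(pairs) == 0:
        raise ValueError("penalty requires at least one shape point pair")
    mapped = t.apply(pairs.p_f)
    resvec = pairs.p_m - mapped  # (N, 3)
    norms = np.linalg.norm(resvec, axis=1)
    active = norms > RESIDUAL_EPS
    grad = np.zeros(t.ffd.n_parameters)
    if np.any(active):
        eval_pts = t.ffd_eval_points(pairs.p_f[active])
        idx, w, inside = t.ffd.jacobian_struct(eval_pts)
        unit = resvec[active] / norms[active, None]
        scale = -1.0 / len(pairs)
        w = np.where(inside[:, None], w, 0.0)
        flat = (idx * 3)[:, :, None] + np.arange(3)[None, None, :]
        np.add.at(grad, flat.ravel(), (scale * w[:, :, None] * unit[:, None, :]).ravel())
    return grad.reshape(t.ffd.coefficients.shape)


def penalty_with_gradient(pairs: ShapePointPairs, t: CombinedTransform) -> PenaltyResult:
    out = penalty(pairs, t)
    out.gradient = penalty_gradient(pairs, t)
    return out
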