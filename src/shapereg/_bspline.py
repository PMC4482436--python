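"""Tensor-product cubic B-spline primitives.

Shared by the free-form deformation transform (control-point lattice in mm)
and the differentiable scalar-field interpolator (voxel lattice).  Everything
is vectorized over query points; weights are returned for the 4x4x4 support
so callers can reuse them for analytic parameter Jacobians.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage


def bspline_weights(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis weights for the 4 support nodes.

    Parameters
    ----------
    t : array, shape (N,)
        Fractional coordinate in [0, 1) relative to the base node.

    Returns
    -------
    array, shape (N, 4)
        Weights for nodes at offsets -1, 0, 1, 2 from the base node.
        Rows sum to 1 (partition of unity).
    """
    t = np.asarray(t, dtype=np.float64)
    t2 = t * t
    t3 = t2 * t
    w = np.empty(t.shape + (4,), dtype=np.float64)
    w[..., 0] = (1.0 - t) ** 3 / 6.0
    w[..., 1] = (3.0 * t3 - 6.0 * t2 + 4.0) / 6.0
    w[..., 2] = (-3.0 * t3 + 3.0 * t2 + 3.0 * t + 1.0) / 6.0
    w[..., 3] = t3 / 6.0
    return w


def bspline_weights_d1(t: np.ndarray) -> np.ndarray:
    """First-derivative weights d/dt of :func:`bspline_weights`."""
    t = np.asarray(t, dtype=np.float64)
    t2 = t * t
    w = np.empty(t.shape + (4,), dtype=np.float64)
    w[..., 0] = -((1.0 - t) ** 2) / 2.0
    w[..., 1] = (9.0 * t2 - 12.0 * t) / 6.0
    w[..., 2] = (-9.0 * t2 + 6.0 * t + 3.0) / 6.0
    w[..., 3] = t2 / 2.0
    return w


def support_indices(u: np.ndarray, n_nodes: tuple[int, int, int]):
    """Base indices, fractions and validity for lattice coordinates ``u``.

    ``u`` is the lattice-normalized coordinate, shape (N, 3).  A point is
    inside the support iff all 4 contributing nodes per axis exist:
    base index i must satisfy 1 <= i <= n-3.
    """
    u = np.asarray(u, dtype=np.float64)
    i = np.floor(u).astype(np.int64)
    t = u - i
    n = np.asarray(n_nodes, dtype=np.int64)
    inside = np.all((i >= 1) & (i <= n - 3), axis=-1)
    return i, t, inside


_OFFSETS = np.array(
    [[a, b, c] for a in range(-1, 3) for b in range(-1, 3) for c in range(-1, 3)],
    dtype=np.int64,
)  # (64, 3), ordering: a-major then b then c


def tensor_weight_struct(u: np.ndarray, n_nodes: tuple[int, int, int],
                         with_derivatives: bool = True):
    """Flat 64-node support structure for points ``u`` in lattice coords.

    Returns
    -------
    idx : (N, 64) int64
        Flat node indices into an (nx, ny, nz) lattice (C order).  Rows of
        points outside the support hold index 0 (weights are still valid;
        callers must mask with ``inside``).
    w : (N, 64) float64
        Tensor-product weights; each row sums to 1.
    dw : (N, 64, 3) float64 or None
        Derivative of ``w`` with respect to each lattice coordinate
        (skipped when ``with_derivatives`` is False).
    inside : (N,) bool
    """
    i, t, inside = support_indices(u, n_nodes)
    wx = bspline_weights(t[:, 0])
    wy = bspline_weights(t[:, 1])
    wz = bspline_weights(t[:, 2])

    # (N, 4, 4, 4) -> (N, 64)
    w = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 64)
    dw = None
    if with_derivatives:
        dwx = bspline_weights_d1(t[:, 0])
        dwy = bspline_weights_d1(t[:, 1])
        dwz = bspline_weights_d1(t[:, 2])
        dw = np.empty((u.shape[0], 64, 3), dtype=np.float64)
        dw[:, :, 0] = (dwx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 64)
        dw[:, :, 1] = (wx[:, :, None, None] * dwy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 64)
        dw[:, :, 2] = (wx[:, :, None, None] * wy[:, None, :, None] * dwz[:, None, None, :]).reshape(-1, 64)

    nx, ny, nz = n_nodes
    off = np.arange(-1, 3, dtype=np.int64)
    ix = np.clip(i[:, 0, None] + off, 0, nx - 1)  # (N, 4)
    iy = np.clip(i[:, 1, None] + off, 0, ny - 1)
    iz = np.clip(i[:, 2, None] + off, 0, nz - 1)
    idx = ((ix[:, :, None, None] * ny + iy[:, None, :, None]) * nz
           + iz[:, None, None, :]).reshape(-1, 64)
    idx[~inside] = 0
    return idx, w, dw, inside


def _mirror_index(idx: np.ndarray, n: int) -> np.ndarray:
    """Reflect indices into [0, n-1] ('mirror' boundary, edge not repeated)."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    idx = np.abs(idx) % period
    return np.where(idx > n - 1, period - idx, idx)


class SplineField:
    """Cubic B-spline interpolator for a stack of scalar volumes.

    Provides values and analytic spatial gradients that are exactly the
    derivatives of the interpolant, so finite differences of downstream
    costs match analytic chain-rule gradients.

    Parameters
    ----------
    data : array, shape (C, nx, ny, nz)
        Channel stack on a voxel grid.
    """

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim == 3:
            data = data[None]
        self.shape = data.shape[1:]
        self.coeffs = np.stack(
            [ndimage.spline_filter(c, order=3, mode="mirror") for c in data]
        ).reshape(data.shape[0], -1)

    def _gather(self, pts_vox: np.ndarray):
        pts = np.asarray(pts_vox, dtype=np.float64)
        i = np.floor(pts).astype(np.int64)
        t = pts - i
        node = i[:, None, :] + _OFFSETS[None, :, :]
        nx, ny, nz = self.shape
        ix = _mirror_index(node[:, :, 0], nx)
        iy = _mirror_index(node[:, :, 1], ny)
        iz = _mirror_index(node[:, :, 2], nz)
        flat = (ix * ny + iy) * nz + iz  # (N, 64)
        vals = self.coeffs[:, flat]  # (C, N, 64)
        return t, vals

    def evaluate(self, pts_vox: np.ndarray) -> np.ndarray:
        """Interpolated values, shape (C, N). Coordinates in voxel units."""
        t, vals = self._gather(pts_vox)
        wx, wy, wz = (bspline_weights(t[:, a]) for a in range(3))
        w = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 64)
        return np.einsum("cnk,nk->cn", vals, w)

    def evaluate_with_gradient(self, pts_vox: np.ndarray):
        """Values (C, N) and spatial gradients (C, N, 3) in 1/voxel units."""
        t, vals = self._gather(pts_vox)
        wx, wy, wz = (bspline_weights(t[:, a]) for a in range(3))
        dwx, dwy, dwz = (bspline_weights_d1(t[:, a]) for a in range(3))
        w = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 64)
        val = np.einsum("cnk,nk->cn", vals, w)
        grad = np.empty(vals.shape[:2] + (3,), dtype=np.float64)
        for axis, wprod in enumerate(
            (
                dwx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :],
                wx[:, :, None, None] * dwy[:, None, :, None] * wz[:, None, None, :],
                wx[:, :, None, None] * wy[:, None, :, None] * dwz[:, None, None, :],
            )
        ):
            grad[:, :, axis] = np.einsum("cnk,nk->cn", vals, wprod.reshape(-1, 64))
        return val, grad


def dyadic_refine_1d(c: np.ndarray, axis: int) -> np.ndarray:
    """Cubic B-spline knot-insertion along one axis (spacing halved).

    New coefficients represent exactly the same spline:
    c'[2i] = (c[i-1] + 6 c[i] + c[i+1]) / 8,  c'[2i+1] = (c[i] + c[i+1]) / 2,
    with out-of-range old coefficients treated as zero.
    """
    c = np.moveaxis(np.asarray(c, dtype=np.float64), axis, 0)
    n = c.shape[0]
    pad = np.zeros((1,) + c.shape[1:], dtype=np.float64)
    cp = np.concatenate([pad, c, pad], axis=0)  # index i -> cp[i+1]
    out = np.empty((2 * n - 1,) + c.shape[1:], dtype=np.float64)
    out[0::2] = (cp[:-2] + 6.0 * cp[1:-1] + cp[2:]) / 8.0
    out[1::2] = (cp[1:-2] + cp[2:-1]) / 2.0
    return np.moveaxis(out, 0, axis)
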