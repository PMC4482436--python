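"""Combined affine + B-spline free-form deformation transform.

The mapping from fixed-image to moving-image world coordinates is

    T(x) = A(x) + u(A(x))

where ``A`` is an affine map (matrix * (x - center) + center + translation)
and ``u`` is the displacement of a cubic B-spline free-form deformation
(FFD) evaluated at the affine-mapped point.  The affine part is fitted once
as an initialization and then frozen; the FFD control-point displacements
are the free parameters mu of the nonrigid optimization.  Evaluating the
FFD at x instead of A(x) is available through ``compose_at_affine=False``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._bspline import dyadic_refine_1d, tensor_weight_struct


@dataclass
class AffineTransform:
    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """matrix @ (p - center) + center + translation, vectorized (N, 3)."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = (p - self.center) @ self.matrix.T + self.center + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]


class FFDTransform:
    """Cubic B-spline FFD displacement field on a regular control lattice.

    Parameters
    ----------
    grid_origin : (3,) mm
        World position of control node (0, 0, 0).
    grid_spacing : (3,) mm
        Control node spacing.
    coefficients : (nx, ny, nz, 3) mm
        Control node displacement vectors; zero coefficients give zero
        displacement everywhere.
    """

    def __init__(self, grid_origin, grid_spacing, coefficients):
        self.grid_origin = np.asarray(grid_origin, dtype=np.float64).reshape(3)
        self.grid_spacing = np.asarray(grid_spacing, dtype=np.float64).reshape(3)
        if np.any(self.grid_spacing <= 0):
            raise ValueError("grid spacing must be positive")
        self.coefficients = np.asarray(coefficients, dtype=np.float64)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")

    @classmethod
    def for_domain(cls, lo, hi, grid_spacing) -> "FFDTransform":
        """Zero FFD whose lattice covers [lo, hi] plus the cubic-support
        margin (at least one extra node beyond each face)."""
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        h = np.broadcast_to(np.asarray(grid_spacing, dtype=np.float64), (3,)).copy()
        origin = lo - 2.0 * h
        n = np.ceil((hi - origin) / h).astype(int) + 4
        return cls(origin, h, np.zeros((*n, 3)))

    @property
    def n_nodes(self):
        return self.coefficients.shape[:3]

    @property
    def n_parameters(self) -> int:
        return self.coefficients.size

    def lattice_coords(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.grid_origin) / self.grid_spacing

    def weight_struct(self, points: np.ndarray, with_derivatives: bool = True):
        """64-node support (flat indices, weights, d-weights, inside mask)."""
        return tensor_weight_struct(self.lattice_coords(points), self.n_nodes,
                                    with_derivatives=with_derivatives)

    def displacement(self, points: np.ndarray, return_inside: bool = False):
        """FFD displacement (mm) at world points; zero outside the support.

        The expansion sum_n c_n B(u - n) is evaluated as a non-prefiltered
        cubic spline interpolation of the coefficient lattice, which is the
        identical tensor product at native speed.
        """
        from scipy import ndimage

        single = np.asarray(points).ndim == 1
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        u = self.lattice_coords(pts)
        i = np.floor(u).astype(np.int64)
        n = np.asarray(self.n_nodes)
        inside = np.all((i >= 1) & (i <= n - 3), axis=1)
        disp = np.empty_like(pts)
        for a in range(3):
            disp[:, a] = ndimage.map_coordinates(
                self.coefficients[..., a], u.T, order=3, prefilter=False,
                mode="constant", cval=0.0)
        disp[~inside] = 0.0
        if single:
            disp, inside = disp[0], inside[0]
        return (disp, inside) if return_inside else disp

    def jacobian_struct(self, points: np.ndarray):
        """Sparse dT/dmu at points: (flat node idx (N,64), weights (N,64),
        inside (N,)).  For coefficient axis a, d T_a / d c[node, a] = weight;
        cross-axis entries are zero."""
        idx, w, _, inside = self.weight_struct(points, with_derivatives=False)
        return idx, w, inside

    def spatial_jacobian(self, points: np.ndarray) -> np.ndarray:
        """du/dx (N, 3, 3), unitless; zero outside the support."""
        idx, _, dw, inside = self.weight_struct(np.atleast_2d(points))
        cflat = self.coefficients.reshape(-1, 3)
        # d disp_d / d x_a = sum_k dw[n,k,a]/h_a * c[k,d]
        jac = np.einsum("nka,nkd->nda", dw, cflat[idx]) / self.grid_spacing[None, None, :]
        jac[~inside] = 0.0
        return jac

    def refine(self) -> "FFDTransform":
        """Halve the grid spacing by knot insertion; represents the same
        deformation exactly."""
        c = self.coefficients
        for ax in range(3):
            c = dyadic_refine_1d(c, ax)
        return FFDTransform(self.grid_origin.copy(), self.grid_spacing / 2.0, c)


@dataclass
class CombinedTransform:
    """Affine initialization plus FFD refinement (T = A + u o A by default)."""

    affine: AffineTransform = field(default_factory=AffineTransform)
    ffd: FFDTransform | None = None
    compose_at_affine: bool = True

    def apply(self, points: np.ndarray) -> np.ndarray:
        single = np.asarray(points).ndim == 1
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        y = self.affine.apply(p)
        if self.ffd is not None:
            y = y + self.ffd.displacement(y if self.compose_at_affine else p)
        return y[0] if single else y

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)

    def ffd_eval_points(self, points: np.ndarray) -> np.ndarray:
        """Points at which the FFD (and its parameter Jacobian) is evaluated."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return self.affine.apply(p) if self.compose_at_affine else p


def identity_transform() -> CombinedTransform:
    return CombinedTransform()


def translation_transform(t) -> CombinedTransform:
    return CombinedTransform(affine=AffineTransform(translation=np.asarray(t, dtype=np.float64)))


def write_transform(t: CombinedTransform, path: str):
    """Plain-text serialization: affine (12 numbers + center), then the FFD
    grid metadata and coefficients row-major."""
    with open(path, "w") as fh:
        fh.write("shapereg-transform 1\n")
        fh.write("affine " + " ".join(f"{v:.17g}" for v in t.affine.matrix.ravel()) + " "
                 + " ".join(f"{v:.17g}" for v in t.affine.translation) + "\n")
        fh.write("center " + " ".join(f"{v:.17g}" for v in t.affine.center) + "\n")
        fh.write(f"compose_at_affine {int(t.compose_at_affine)}\n")
        if t.ffd is None:
            fh.write("ffd none\n")
            return
        fh.write("ffd " + " ".join(str(n) for n in t.ffd.n_nodes) + "\n")
        fh.write("grid_origin " + " ".join(f"{v:.17g}" for v in t.ffd.grid_origin) + "\n")
        fh.write("grid_spacing " + " ".join(f"{v:.17g}" for v in t.ffd.grid_spacing) + "\n")
        for row in t.ffd.coefficients.reshape(-1, 3):
            fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")


def read_transform(path: str) -> CombinedTransform:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("shapereg-transform"):
        raise ValueError(f"not a shapereg transform file: {path}")
    vals = lambda ln: [float(v) for v in ln.split()[1:]]
    aff = vals(lines[1])
    affine = AffineTransform(np.array(aff[:9]).reshape(3, 3), np.array(aff[9:12]),
                             np.array(vals(lines[2])))
    compose = bool(int(lines[3].split()[1]))
    if lines[4].split()[1] == "none":
        return CombinedTransform(affine=affine, ffd=None, compose_at_affine=compose)
    n = [int(v) for v in lines[4].split()[1:]]
    origin = np.array(vals(lines[5]))
    spacing = np.array(vals(lines[6]))
    coeffs = np.array([[float(v) for v in ln.split()] for ln in lines[7:]])
    expected = n[0] * n[1] * n[2]
    if coeffs.shape != (expected, 3):
        raise ValueError(f"expected {expected} coefficient rows, got {coeffs.shape[0]}")
    return CombinedTransform(affine=affine, compose_at_affine=compose,
                             ffd=FFDTransform(origin, spacing, coeffs.reshape(*n, 3)))
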