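"""Per-voxel feature stacks for the multifeature mutual-information metric.

Each voxel is described by a d-dimensional feature vector: the raw
intensity L, six rotation-invariant Cartesian features built from the
Gaussian-derivative gradient g and Hessian H at each scale
(g'g, g'Hg, g'HHg, tr H, tr HH, tr HHH), and the gradient orientation
angles (theta, phi) at each scale.  With the default scales {1, 2} this
gives d = 1 + 6*2 + 2*2 = 17 channels.  Channels are z-score normalized
over a sample of fixed-image points; the same affine normalization is then
applied to the moving stack so the joint feature space is consistent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume


def gaussian_derivatives(vol: Volume, sigma: float, mm_scale: bool = False):
    """First and second Gaussian-derivative responses at scale ``sigma``.

    Returns
    -------
    g : ndarray, shape (*vol.shape, 3)
        Gradient field (per-voxel units unless ``mm_scale``).
    H : ndarray, shape (*vol.shape, 3, 3)
        Symmetric Hessian field.

    ``sigma`` is in voxel units by default; with ``mm_scale=True`` it is in
    mm and divided by the per-axis spacing (spacing-aware derivatives).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data = vol.data.astype(np.float64)
    if mm_scale:
        sig = sigma / vol.spacing
    else:
        sig = np.full(3, float(sigma))
    g = np.empty(data.shape + (3,))
    H = np.empty(data.shape + (3, 3))
    # truncate=6 keeps the discrete derivative kernels close to zero-sum
    for a in range(3):
        order = [0, 0, 0]
        order[a] = 1
        g[..., a] = ndimage.gaussian_filter(data, sig, order=order, mode="nearest",
                                            truncate=6.0)
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            H[..., a, b] = ndimage.gaussian_filter(data, sig, order=order,
                                                   mode="nearest", truncate=6.0)
            H[..., b, a] = H[..., a, b]
    return g, H


def cartesian_features(L, g, H) -> np.ndarray:
    """(g'g, g'Hg, g'HHg, tr H, tr HH, tr HHH); broadcasts over leading axes.

    ``L`` is accepted for signature completeness (the intensity channel is
    carried separately in the stack).
    """
    g = np.asarray(g, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    Hg = np.einsum("...ab,...b->...a", H, g)
    HH = np.einsum("...ab,...bc->...ac", H, H)
    out = np.stack(
        [
            np.einsum("...a,...a->...", g, g),
            np.einsum("...a,...a->...", g, Hg),
            np.einsum("...a,...a->...", Hg, Hg),  # g'HHg with symmetric H
            np.trace(H, axis1=-2, axis2=-1),
            np.trace(HH, axis1=-2, axis2=-1),
            np.einsum("...ab,...ba->...", HH, H),
        ],
        axis=-1,
    )
    return out


def gradient_orientation(g, eps: float = 1e-12):
    """Orientation angles of gradient vectors (v1, v2, v3).

    theta = arccos(v3 / r) in [0, pi] with r = |g|; phi is the
    full-quadrant arctangent of (v1, v2) in (-pi, pi].  Degenerate inputs
    (r ~ 0 for theta; v1 = v2 = 0 for phi) yield sentinel 0 with the
    returned flag set.  Both angles are invariant to positive scaling of g.

    Returns (theta, phi, degenerate).
    """
    g = np.asarray(g, dtype=np.float64)
    v1, v2, v3 = g[..., 0], g[..., 1], g[..., 2]
    r = np.sqrt(v1 * v1 + v2 * v2 + v3 * v3)
    rho = np.hypot(v1, v2)
    theta = np.where(r > eps, np.arccos(np.clip(np.divide(v3, np.where(r > eps, r, 1.0)), -1, 1)), 0.0)
    phi = np.where(rho > eps, np.arctan2(v1, v2), 0.0)
    degenerate = rho <= eps  # covers r ~ 0 as well
    return theta, phi, degenerate


@dataclass
class FeatureStack:
    """Ordered per-voxel feature channels on a volume grid.

    channels : (d, nx, ny, nz); names label each channel; scales are the
    Gaussian scales used; degenerate flags voxels whose orientation angles
    were sentinel-filled; normalization holds per-channel (mean, std) once
    :func:`normalize_features` has run.
    """

    channels: np.ndarray
    names: list
    scales: list
    spacing: np.ndarray
    origin: np.ndarray
    degenerate: np.ndarray | None = None
    normalization: np.ndarray | None = None  # (d, 2): mean, std

    @property
    def d(self) -> int:
        return self.channels.shape[0]

    def voxel(self, world_points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(world_points) - self.origin) / self.spacing

    def sample(self, world_points: np.ndarray, order: int = 1) -> np.ndarray:
        """Linear interpolation of all channels at world points -> (N, d)."""
        vox = self.voxel(world_points).T
        out = np.empty((len(self.channels), vox.shape[1]))
        for c, ch in enumerate(self.channels):
            out[c] = ndimage.map_coordinates(ch, vox, order=order, mode="nearest")
        return out.T

    def channel_volume(self, index: int) -> Volume:
        """Expose one channel as a Volume (for inspection dumps)."""
        return Volume(self.channels[index].copy(), self.spacing.copy(), self.origin.copy())


def assemble_feature_stack(vol: Volume, scales=(1.0, 2.0), mm_scale: bool = False) -> FeatureStack:
    """Build the feature stack [L, per-scale Cartesian x6, per-scale (theta, phi)]."""
    scales = list(scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be non-empty and positive")
    data = vol.data.astype(np.float64)
    d = 1 + 8 * len(scales)
    channels = np.empty((d,) + data.shape)
    channels[0] = data
    names = ["L"]
    onames = []
    degenerate = np.zeros(data.shape, dtype=bool)
    n_orient_base = 1 + 6 * len(scales)
    for si, s in enumerate(scales):
        g, H = gaussian_derivatives(vol, s, mm_scale=mm_scale)
        cart = cartesian_features(data, g, H)
        for j, nm in enumerate(("gTg", "gTHg", "gTHHg", "trH", "trHH", "trHHH")):
            channels[1 + 6 * si + j] = cart[..., j]
            names.append(f"{nm}@{s:g}")
        th, ph, deg = gradient_orientation(g)
        channels[n_orient_base + 2 * si] = th
        channels[n_orient_base + 2 * si + 1] = ph
        onames += [f"theta@{s:g}", f"phi@{s:g}"]
        degenerate |= deg
    names += onames
    return FeatureStack(
        channels=channels,
        names=names,
        scales=scales,
        spacing=vol.spacing.copy(),
        origin=vol.origin.copy(),
        degenerate=degenerate,
    )


def normalize_features(fs: FeatureStack, sample_points: np.ndarray, tol: float = 1e-12) -> FeatureStack:
    """Z-score each channel using statistics over ``sample_points`` (mm).

    Population (ddof=0) statistics.  Channels that are constant over the
    samples carry no information and are dropped with a warning.  Returns a
    new stack whose stored (mean, std) can be re-applied to another stack
    via :func:`apply_normalization`.
    """
    pts = np.atleast_2d(sample_points)
    if len(pts) < 2:
        raise ValueError("need at least 2 sample points to normalize")
    vals = fs.sample(pts)  # (N, d)
    mean = vals.mean(axis=0)
    std = vals.std(axis=0)
    keep = std > tol
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} constant feature channel(s): "
            f"{[fs.names[i] for i in np.nonzero(~keep)[0]]}"
        )
    norm = np.stack([mean[keep], std[keep]], axis=1)
    chans = (fs.channels[keep] - mean[keep, None, None, None]) / std[keep, None, None, None]
    return FeatureStack(
        channels=chans,
        names=[n for n, k in zip(fs.names, keep) if k],
        scales=list(fs.scales),
        spacing=fs.spacing.copy(),
        origin=fs.origin.copy(),
        degenerate=None if fs.degenerate is None else fs.degenerate.copy(),
        normalization=norm,
    )


def apply_normalization(fs: FeatureStack, normalization: np.ndarray, names: list) -> FeatureStack:
    """Apply previously estimated per-channel (mean, std) to another stack,
    keeping only the channels named in ``names`` (fixed/moving consistency)."""
    index = {n: i for i, n in enumerate(fs.names)}
    sel = [index[n] for n in names]
    mean = normalization[:, 0]
    std = normalization[:, 1]
    chans = (fs.channels[sel] - mean[:, None, None, None]) / std[:, None, None, None]
    return FeatureStack(
        channels=chans,
        names=list(names),
        scales=list(fs.scales),
        spacing=fs.spacing.copy(),
        origin=fs.origin.copy(),
        degenerate=None if fs.degenerate is None else fs.degenerate.copy(),
        normalization=normalization.copy(),
    )
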