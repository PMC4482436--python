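"""Volumetric containers, file I/O, resampling and coordinate conversions.

Images are stored as ``(nx, ny, nz)`` float arrays with spacing/origin
metadata; world coordinates are physical millimetres, ``world = origin +
index * spacing`` (axis-aligned direction cosines, node-centered voxels,
0-based indices).  MetaImage (.mha/.mhd) and NIfTI (.nii/.nii.gz) files are
read and written through SimpleITK.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

#: label codes used for cardiac structures throughout the package
CARDIAC_LABELS = {"AO": 1, "LV": 2, "LVM": 3, "LA": 4, "RV": 5, "RA": 6}

_SUPPORTED_EXT = (".mha", ".mhd", ".nii", ".nii.gz")


class VolumeFormatError(ValueError):
    """Unsupported or corrupt volume file."""


@dataclass
class Volume:
    """A 3-D scalar image with grid metadata.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (Hounsfield-like arbitrary units).
    spacing : ndarray, shape (3,)
        Voxel size in mm along each axis; strictly positive.
    origin : ndarray, shape (3,)
        World coordinate (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got {self.data.ndim}-D")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be strictly positive")

    @property
    def size(self) -> np.ndarray:
        return np.asarray(self.data.shape)

    def world(self, voxel: np.ndarray) -> np.ndarray:
        """Voxel indices (possibly fractional) -> world mm."""
        return self.origin + np.asarray(voxel, dtype=np.float64) * self.spacing

    def voxel(self, world: np.ndarray) -> np.ndarray:
        """World mm -> (fractional) voxel indices."""
        return (np.asarray(world, dtype=np.float64) - self.origin) / self.spacing

    def domain(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space bounding box (lo, hi) of the voxel grid, mm."""
        return self.origin.copy(), self.world(self.size - 1)

    def grid_points(self, step: int = 1) -> np.ndarray:
        """World coordinates of every ``step``-th grid node, shape (N, 3)."""
        ax = [np.arange(0, n, step) for n in self.data.shape]
        ii, jj, kk = np.meshgrid(*ax, indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.world(idx)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelVolume(Volume):
    """Integer segmentation volume; 0 is background.

    ``labels`` maps structure names (AO, LV, LVM, LA, RV, RA by default)
    to their integer codes.
    """

    labels: dict = field(default_factory=lambda: dict(CARDIAC_LABELS))

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = np.round(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label codes must be non-negative")

    def mask(self, label) -> np.ndarray:
        """Boolean mask for a label given by code or name."""
        code = self.labels.get(label, label) if isinstance(label, str) else label
        return self.data == code

    def present_labels(self) -> list[int]:
        codes = np.unique(self.data)
        return [int(c) for c in codes if c != 0]


def read_volume(path: str, label: bool = False) -> Volume:
    """Read a MetaImage or NIfTI volume.

    Spacing and origin are taken from the header; intensities are not
    rescaled.  Direction cosines must be axis-aligned (identity).
    """
    low = str(path).lower()
    if not any(low.endswith(e) for e in _SUPPORTED_EXT):
        raise VolumeFormatError(f"unsupported volume format: {path}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # corrupt header, truncated file ...
        raise VolumeFormatError(f"cannot parse {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(f"expected a 3-D volume, got {img.GetDimension()}-D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeFormatError("only axis-aligned (identity direction) volumes are supported")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
    cls = LabelVolume if label else Volume
    return cls(data=data, spacing=np.asarray(img.GetSpacing()), origin=np.asarray(img.GetOrigin()))


def write_volume(vol: Volume, path: str):
    """Write a volume as MetaImage or NIfTI (chosen by extension)."""
    low = str(path).lower()
    if not any(low.endswith(e) for e in _SUPPORTED_EXT):
        raise VolumeFormatError(f"unsupported volume format: {path}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_landmarks(path: str) -> np.ndarray:
    """Read a landmark file: first line N, then N lines of ``x y z`` (mm)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty landmark file: {path}")
    try:
        n = int(lines[0])
    except ValueError as exc:
        raise ValueError(f"first line must be the point count: {path}") from exc
    rows = lines[1:]
    if len(rows) != n:
        raise ValueError(f"landmark file declares {n} points but contains {len(rows)}")
    pts = np.array([[float(v) for v in r.split()] for r in rows], dtype=np.float64)
    if pts.size and pts.shape[1] != 3:
        raise ValueError("each landmark line must hold exactly 3 coordinates")
    return pts.reshape(-1, 3)


def write_landmarks(points: np.ndarray, path: str):
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"{len(points)}\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def resample(moving: Volume, transform, reference: Volume, interpolation: str = "linear"):
    """Resample ``moving`` onto ``reference``'s grid through ``transform``.

    Each output voxel at world point x holds ``moving`` interpolated at
    T(x); points mapping outside the moving domain are filled with 0
    (background for labels).  Nearest-neighbour interpolation is forced for
    label volumes so no new label codes can appear.
    """
    is_label = isinstance(moving, LabelVolume)
    if is_label:
        interpolation = "nearest"
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    pts = reference.grid_points()
    mapped = transform(pts) if callable(transform) else transform.apply(pts)
    vox = moving.voxel(mapped).T  # (3, N)
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        moving.data.astype(np.float64), vox, order=order, mode="constant", cval=0.0
    )
    out = out.reshape(reference.data.shape)
    if is_label:
        out = np.round(out).astype(moving.data.dtype)
        return LabelVolume(
            data=out, spacing=reference.spacing.copy(), origin=reference.origin.copy(),
            labels=dict(moving.labels),
        )
    return Volume(data=out, spacing=reference.spacing.copy(), origin=reference.origin.copy())


def outside_mask(moving: Volume, transform, reference: Volume) -> np.ndarray:
    """Boolean volume on the reference grid flagging voxels whose mapped
    point falls outside the moving domain (so metrics can exclude them)."""
    pts = reference.grid_points()
    mapped = transform(pts) if callable(transform) else transform.apply(pts)
    vox = moving.voxel(mapped)
    hi = np.asarray(moving.data.shape) - 1
    out = np.any((vox < 0) | (vox > hi), axis=1)
    return out.reshape(reference.data.shape)


def gaussian_smooth(vol: Volume, sigma_vox: float) -> Volume:
    """Gaussian smoothing (sigma in voxels), grid metadata preserved."""
    if sigma_vox <= 0:
        return Volume(vol.data.astype(np.float64), vol.spacing.copy(), vol.origin.copy())
    sm = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma_vox, mode="nearest")
    return Volume(sm, vol.spacing.copy(), vol.origin.copy())
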