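"""NIfTI I/O and affine-stage preprocessing.

Array axes (x, y, z) map to NIfTI (i, j, k); internal coordinates are
voxel-indexed (0-based) or normalized [-1, 1] — world/scanner space is only
touched at I/O.  The standard preprocessing chain for a scan entering
registration is: temporal mean (4-D), resample to the target spacing, pad or
crop to the target shape, min-max normalize to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class PreprocSpec:
    """Target grid of the registration stage."""

    shape: tuple = (96, 96, 48)
    spacing: tuple = (0.3, 0.3, 0.4)   # mm

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")


@dataclass
class VolumeImage:
    """A loaded NIfTI volume (3-D) or series (4-D) with its grid metadata."""

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray

    @property
    def is_series(self) -> bool:
        return self.data.ndim == 4


def load_volume(path) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3-D or 4-D NIfTI, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data=data, spacing=spacing, affine=np.asarray(img.affine))


def save_volume(vol: VolumeImage | np.ndarray, path, spacing=None, affine=None) -> None:
    if isinstance(vol, VolumeImage):
        data, affine = vol.data, vol.affine
    else:
        data = np.asarray(vol)
        if affine is None:
            sp = spacing or (1.0, 1.0, 1.0)
            affine = np.diag(list(sp) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    if spacing is not None:
        img.header.set_zooms(tuple(spacing) + (() if data.ndim == 3 else (1.0,)))
    nib.save(img, str(path))


def temporal_mean(series: np.ndarray) -> np.ndarray:
    """Voxel-wise mean over the time axis of a 4-D series."""
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 4:
        raise ValueError("temporal_mean expects a 4-D series (X, Y, Z, T)")
    if series.shape[3] == 0:
        raise ValueError("empty time series")
    return series.mean(axis=3)


def resample_pad(volume: np.ndarray, spacing, spec: PreprocSpec) -> np.ndarray:
    """Trilinear resample to the target spacing, then symmetric zero-pad or
    centre-crop to the target shape."""
    volume = np.asarray(volume, dtype=np.float64)
    zoom = [s_in / s_out for s_in, s_out in zip(spacing, spec.spacing)]
    resampled = ndimage.zoom(volume, zoom, order=1, mode="grid-constant", cval=0.0,
                             grid_mode=True)
    out = resampled
    for ax, target in enumerate(spec.shape):
        n = out.shape[ax]
        if n < target:
            lo = (target - n) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (lo, target - n - lo)
            out = np.pad(out, pad)
        elif n > target:
            lo = (n - target) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(lo, lo + target)
            out = out[tuple(sl)]
    return out


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; constant input maps to zeros."""
    volume = np.asarray(volume, dtype=np.float64)
    vmin, vmax = volume.min(), volume.max()
    if vmax == vmin:
        warnings.warn("constant-intensity volume; normalized to zeros")
        return np.zeros_like(volume)
    return (volume - vmin) / (vmax - vmin)


def preprocess(image: VolumeImage, spec: PreprocSpec | None = None) -> np.ndarray:
    """Full chain: temporal mean (if 4-D) -> resample/pad -> normalize."""
    spec = spec or PreprocSpec()
    data = temporal_mean(image.data) if image.is_series else image.data
    data = resample_pad(data, image.spacing, spec)
    return normalize_intensity(data)


def normalized_to_voxel_matrix(matrix: np.ndarray, shape) -> np.ndarray:
    """Convert a sampling matrix from the normalized frame to voxel indices.

    With ``P`` the per-axis map v = (g + 1) (N - 1)/2, the voxel-space
    sampling matrix is ``P A P^-1``."""
    p = np.eye(4)
    for ax, n in enumerate(shape):
        p[ax, ax] = (n - 1) / 2.0
        p[ax, 3] = (n - 1) / 2.0
    return p @ matrix @ np.linalg.inv(p)


def voxel_to_world_matrix(voxel_matrix: np.ndarray, fixed_affine: np.ndarray,
                          moving_affine: np.ndarray) -> np.ndarray:
    """World-space sampling matrix: maps fixed-world points to the moving-world
    points they sample from (``W_m V W_f^-1``)."""
    return moving_affine @ voxel_matrix @ np.linalg.inv(fixed_affine)
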