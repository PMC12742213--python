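"""Spatial-transformer warping: affine sampling grids and resampling.

Pull (backward) warping throughout: for each voxel of the *target* grid the
sampling grid stores the normalized coordinate in the *moving* image the value
is read from, so the output has no holes and out-of-bounds reads are zero.
Intensity images are resampled trilinearly; label maps nearest-neighbour.
"""

from __future__ import annotations

import numpy as np

from . import _tensor
from ._tensor import Tensor
from .geometry import AffineTransform


def _normalized_mesh(shape) -> np.ndarray:
    """(N, 4) homogeneous normalized coordinates of all voxel centres."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)
    return np.concatenate([coords, np.ones((coords.shape[0], 1))], axis=1)


def affine_grid(transform: AffineTransform, shape) -> np.ndarray:
    """Sampling grid: the transform applied to every target voxel centre.

    Returns an array of shape ``shape + (3,)`` holding, per target voxel, the
    normalized source coordinate to sample the moving image at.
    """
    shape = tuple(int(n) for n in shape)
    if any(n <= 0 for n in shape):
        raise ValueError(f"grid shape must be positive, got {shape}")
    coords = _normalized_mesh(shape)
    out = coords @ transform.matrix.T
    return out[:, :3].reshape(shape + (3,))


def _sample(volume: np.ndarray, grid_flat: np.ndarray, interpolation: str) -> np.ndarray:
    if interpolation == "trilinear":
        return _tensor.grid_sample3d(Tensor(volume), grid_flat).data
    if interpolation == "nearest":
        vox = np.empty_like(grid_flat)
        for ax in range(3):
            vox[:, ax] = (grid_flat[:, ax] + 1.0) * 0.5 * (volume.shape[ax] - 1)
        idx = np.round(vox).astype(np.int64)
        valid = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
        idx_c = np.clip(idx, 0, np.array(volume.shape) - 1)
        vals = volume[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
        return np.where(valid, vals, 0)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def warp_volume(moving: np.ndarray, transform: AffineTransform,
                interpolation: str = "trilinear", shape=None) -> np.ndarray:
    """Resample ``moving`` through the affine sampling transform.

    ``shape`` defaults to the moving image's own shape.  Nearest-neighbour
    interpolation preserves the input dtype (for label maps).
    """
    moving = np.asarray(moving)
    if not np.all(np.isfinite(moving)):
        raise ValueError("moving image must be finite-valued")
    target = tuple(shape) if shape is not None else moving.shape
    grid = affine_grid(transform, target).reshape(-1, 3)
    out = _sample(moving.astype(np.float64) if interpolation == "trilinear" else moving,
                  grid, interpolation)
    out = out.reshape(target)
    if interpolation == "nearest":
        out = out.astype(moving.dtype)
    return out


def warp_timeseries(series: np.ndarray, transform: AffineTransform) -> np.ndarray:
    """Apply one affine transform to every frame of a 4-D series (X,Y,Z,T)."""
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError("expected a 4-D series (X, Y, Z, T)")
    if series.shape[3] == 0:
        raise ValueError("empty time series")
    grid = affine_grid(transform, series.shape[:3]).reshape(-1, 3)
    out = np.empty_like(series, dtype=np.float64)
    for t in range(series.shape[3]):
        out[..., t] = _sample(series[..., t].astype(np.float64), grid,
                              "trilinear").reshape(series.shape[:3])
    return out


# ---------------------------------------------------------------------------
# differentiable path
# ---------------------------------------------------------------------------

def warp_volume_t(moving, matrix_t: Tensor, shape) -> Tensor:
    """Differentiable trilinear warp; gradient flows into ``matrix_t`` (and
    into ``moving`` when it is a Tensor)."""
    shape = tuple(int(n) for n in shape)
    coords = _normalized_mesh(shape)  # (N, 4) constant
    grid = Tensor(coords) @ matrix_t.swapaxes(0, 1)
    grid3 = grid[:, 0:3]
    vol = moving if isinstance(moving, Tensor) else Tensor(np.asarray(moving, dtype=np.float64))
    return _tensor.grid_sample3d(vol, grid3).reshape(shape)


def downsample_half_t(volume: Tensor) -> Tensor:
    """Trilinear 2x downsampling (each axis halved), differentiable.

    Samples at the coarse voxel centres (source position 2j + 0.5), so each
    output voxel is the trilinear — here exact 8-neighbour — average of its
    source block and the mean intensity is preserved."""
    shape = tuple(n // 2 for n in volume.shape)
    axes = [(2.0 * np.arange(m) + 0.5) / (n - 1) * 2.0 - 1.0
            for m, n in zip(shape, volume.shape)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)
    return _tensor.grid_sample3d(volume, coords).reshape(shape)
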