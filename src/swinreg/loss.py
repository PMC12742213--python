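"""Unsupervised registration objective.

Similarity: windowed local normalized cross-correlation (NCC) summed over an
image pyramid with weights -1/2**(L-i) (finest level i=L weighs -1, then
-1/2, -1/4, ...), so identical pyramids at L=3 give approximately -1.75.
Regularisation: a dimensionless quadratic identity-deviation on the geometric
parameters, weighted by lambda (default 0.01).

Local NCC per voxel over a w^3 neighbourhood (clipped at the volume border,
statistics over the in-bounds window population only):

    ncc(p) = sum (F-Fbar)(W-Wbar) / sqrt(sum (F-Fbar)^2 * sum (W-Wbar)^2 + eps)

with eps = 1e-5 guarding flat windows (which then contribute 0, not NaN); the
image score is the mean over voxels, lies in [-1, 1] up to eps effects, and is
invariant to local affine intensity changes a*W + b (a > 0) everywhere,
including border windows.  ``w = 0`` is a sentinel for global NCC (one window
spanning the image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor
from ._tensor import Tensor, box_sum3d
from .geometry import AffineTransform, GeometricParams
from .network import build_pyramid
from .warp import warp_volume_t

DEFAULT_WINDOW = 7
DEFAULT_LAMBDA = 0.01
EPS = 1e-5


@dataclass
class LossBreakdown:
    sim: float
    reg: float
    lam: float

    @property
    def total(self) -> float:
        return self.sim + self.lam * self.reg


def local_ncc_t(fixed: np.ndarray, warped: Tensor, window: int = DEFAULT_WINDOW) -> Tensor:
    """Differentiable local NCC (scalar Tensor); ``fixed`` is constant."""
    f = np.asarray(fixed, dtype=np.float64)
    if tuple(warped.shape) != f.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {tuple(warped.shape)}")
    if window == 0:
        n = float(f.size)
        fc = f - f.mean()
        wc = warped - warped.mean()
        cross = (Tensor(fc) * wc).sum()
        var_f = float((fc * fc).sum())
        var_w = (wc * wc).sum()
        return cross / (var_f * var_w + EPS).sqrt()
    if window % 2 == 0 or window < 0:
        raise ValueError("NCC window must be odd (or 0 for global)")
    with _tensor.no_grad():
        n = box_sum3d(Tensor(np.ones_like(f)), window).data  # in-bounds counts
    sf = box_sum3d(Tensor(f), window).data
    sff = box_sum3d(Tensor(f * f), window).data
    sw = box_sum3d(warped, window)
    sww = box_sum3d(warped * warped, window)
    sfw = box_sum3d(warped * f, window)
    # centred sums via sufficient statistics
    cross = sfw - sw * (sf / n)
    var_f = np.maximum(sff - sf * sf / n, 0.0)
    var_w = sww - sw * sw * (1.0 / n)
    ncc = cross / (var_w * var_f + EPS).sqrt()
    return ncc.mean()


def local_ncc(fixed: np.ndarray, warped: np.ndarray, window: int = DEFAULT_WINDOW) -> float:
    with _tensor.no_grad():
        return float(local_ncc_t(fixed, Tensor(np.asarray(warped, dtype=np.float64)),
                                 window).item())


def similarity_loss_t(fixed_pyr: list[np.ndarray], warped_pyr: list[Tensor],
                      window: int = DEFAULT_WINDOW) -> Tensor:
    """Weighted multi-resolution negative NCC; level i (1-based, coarse to
    fine) weighs -1/2**(L-i).  Lower is better."""
    if len(fixed_pyr) != len(warped_pyr):
        raise ValueError("pyramids must have equal length")
    levels = len(fixed_pyr)
    total = Tensor(0.0)
    for i, (f_i, w_i) in enumerate(zip(fixed_pyr, warped_pyr), start=1):
        weight = -1.0 / 2 ** (levels - i)
        total = total + weight * local_ncc_t(f_i, w_i, window)
    return total


def similarity_loss(fixed_pyr: list[np.ndarray], warped_pyr: list[np.ndarray],
                    window: int = DEFAULT_WINDOW) -> float:
    with _tensor.no_grad():
        wp = [Tensor(np.asarray(w, dtype=np.float64)) for w in warped_pyr]
        return float(similarity_loss_t(fixed_pyr, wp, window).item())


def regularization_t(params: Tensor) -> Tensor:
    """Quadratic identity-deviation on a constrained [t, r, s, h] 12-vector:
    sum t^2 + sum (r/pi)^2 + sum ((s-1)/0.5)^2 + sum (h/pi)^2."""
    t, r, s, h = params[0:3], params[3:6], params[6:9], params[9:12]
    return ((t * t).sum() + ((r * (1 / np.pi)) ** 2).sum()
            + (((s - 1.0) * 2.0) ** 2).sum() + ((h * (1 / np.pi)) ** 2).sum())


def regularization(params: GeometricParams) -> float:
    params.validate()
    with _tensor.no_grad():
        return float(regularization_t(Tensor(params.as_vector())).item())


def total_loss(fixed: np.ndarray, moving: np.ndarray, transform: AffineTransform,
               params: GeometricParams, lam: float = DEFAULT_LAMBDA,
               levels: int = 3, window: int = DEFAULT_WINDOW) -> LossBreakdown:
    """Warp the moving image, build both pyramids, return sim + lambda*reg."""
    from .warp import warp_volume

    warped = warp_volume(np.asarray(moving, dtype=np.float64), transform)
    f_pyr = build_pyramid(fixed, levels)
    w_pyr = build_pyramid(warped, levels)
    sim = similarity_loss(f_pyr, w_pyr, window)
    reg = regularization(params)
    return LossBreakdown(sim=sim, reg=reg, lam=lam)


def training_loss_t(fixed: np.ndarray, fixed_pyr: list[np.ndarray], moving: np.ndarray,
                    transform_t: Tensor, stage_params_t: list[Tensor],
                    lam: float = DEFAULT_LAMBDA,
                    window: int = DEFAULT_WINDOW) -> tuple[Tensor, float, float]:
    """End-to-end differentiable loss for one pair: the moving image is warped
    once by the accumulated transform, downsampled into a pyramid, and scored;
    each stage's parameter deviation is regularised.  Returns (loss Tensor,
    sim value, reg value)."""
    from .warp import downsample_half_t

    levels = len(fixed_pyr)
    warped = warp_volume_t(moving, transform_t, np.asarray(fixed).shape)
    w_pyr = [warped]
    for _ in range(levels - 1):
        w_pyr.append(downsample_half_t(w_pyr[-1]))
    w_pyr = w_pyr[::-1]
    sim = similarity_loss_t(fixed_pyr, w_pyr, window)
    reg = Tensor(0.0)
    for p in stage_params_t:
        reg = reg + regularization_t(p)
    loss = sim + lam * reg
    return loss, float(sim.item()), float(reg.item())
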