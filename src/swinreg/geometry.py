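"""Geometric transformation model for 3-D affine registration.

An affine alignment is parameterised by twelve scalars — translation ``t``,
Euler rotation ``r`` (radians, applied as ``R_x R_y R_z``), anisotropic scale
``s`` and upper-triangular shear ``h`` — composed in the fixed order

    A = T @ (R @ S @ H)                                  (about a pivot)

All matrices act in a normalized coordinate frame: each axis of the volume is
mapped to [-1, 1] with the origin at the geometric centre and voxel centres at
the interval ends, so parameters are resolution independent across pyramid
levels.  Rotation, scale and shear pivot about a centre point (by default the
moving image's centre of mass); translation components are expressed as a
fraction of the half-extent, i.e. ``t_x = 0.5`` moves by half of one
normalized half-axis.

Admissible ranges (enforced smoothly via ``tanh`` in :func:`constrain_params`):
rotation and shear in [-pi, pi], translation in [-0.5, 0.5], scale in
[0.5, 1.5].  Within these ranges the linear block always has positive
determinant, so reflections cannot occur.

Matrices are *sampling* (pull) transforms: warping a moving image M by A
produces ``W(x) = M(A x)``.  Consequently applying stage transforms
sequentially (stage 1 first) is equivalent to one warp by the left-to-right
matrix product — see :func:`accumulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor
from ._tensor import Tensor

NORMALIZED_CONVENTION = "normalized[-1,1],origin=center,axes=xyz,pull"

TRANSLATION_BOUND = 0.5
ROTATION_BOUND = np.pi
SHEAR_BOUND = np.pi
SCALE_RANGE = (0.5, 1.5)


class RangeError(ValueError):
    """A geometric parameter lies outside its admissible range."""


class DegenerateImageError(ValueError):
    """The image has no mass (all zero), so its centre of mass is undefined."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeometricParams:
    """The 12 affine degrees of freedom [t, r, s, h]."""

    t: np.ndarray  # translation (t_x, t_y, t_z), fraction of half-extent
    r: np.ndarray  # rotation (r_x, r_y, r_z), radians
    s: np.ndarray  # scale (s_x, s_y, s_z)
    h: np.ndarray  # shear (h_xy, h_xz, h_yz)

    def __post_init__(self):
        for name in ("t", "r", "s", "h"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a triple, got shape {v.shape}")
            setattr(self, name, v)
        self.validate()

    def validate(self) -> None:
        if np.any(np.abs(self.t) > TRANSLATION_BOUND + 1e-12):
            raise RangeError(f"translation outside [-0.5, 0.5]: {self.t}")
        if np.any(np.abs(self.r) > ROTATION_BOUND + 1e-12):
            raise RangeError(f"rotation outside [-pi, pi]: {self.r}")
        if np.any(np.abs(self.h) > SHEAR_BOUND + 1e-12):
            raise RangeError(f"shear outside [-pi, pi]: {self.h}")
        if np.any(self.s < SCALE_RANGE[0] - 1e-12) or np.any(self.s > SCALE_RANGE[1] + 1e-12):
            raise RangeError(f"scale outside [0.5, 1.5]: {self.s}")

    @classmethod
    def identity(cls) -> "GeometricParams":
        return cls(t=np.zeros(3), r=np.zeros(3), s=np.ones(3), h=np.zeros(3))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.t, self.r, self.s, self.h])

    @classmethod
    def from_vector(cls, v) -> "GeometricParams":
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (12,):
            raise ValueError("parameter vector must have 12 entries")
        return cls(t=v[0:3], r=v[3:6], s=v[6:9], h=v[9:12])

    def to_dict(self) -> dict:
        return {"t": self.t.tolist(), "r": self.r.tolist(),
                "s": self.s.tolist(), "h": self.h.tolist()}


@dataclass
class AffineTransform:
    """4x4 homogeneous matrix plus the coordinate convention it acts in."""

    matrix: np.ndarray
    convention: str = NORMALIZED_CONVENTION

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("bottom row of an affine matrix must be (0,0,0,1)")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.convention)

    def compose_with(self, other: "AffineTransform") -> "AffineTransform":
        if self.convention != other.convention:
            raise ValueError("cannot compose transforms in different conventions")
        return AffineTransform(self.matrix @ other.matrix, self.convention)

    # -- serialisation (plain-text matrix + JSON parameter sidecar) ----------
    def to_text(self) -> str:
        return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in self.matrix) + "\n"

    @classmethod
    def from_text(cls, text: str, convention: str = NORMALIZED_CONVENTION) -> "AffineTransform":
        rows = [[float(v) for v in line.split()] for line in text.strip().splitlines()]
        return cls(np.array(rows), convention)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "AffineTransform":
        with open(path) as fh:
            return cls.from_text(fh.read())


# ---------------------------------------------------------------------------
# elementary matrices
# ---------------------------------------------------------------------------

def translation_matrix(t) -> AffineTransform:
    t = np.asarray(t, dtype=np.float64)
    m = np.eye(4)
    m[:3, 3] = t
    return AffineTransform(m)


def rotation_matrix(r) -> AffineTransform:
    """Euler rotation R = R_x(r_x) @ R_y(r_y) @ R_z(r_z)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) > ROTATION_BOUND + 1e-12):
        raise RangeError(f"rotation outside [-pi, pi]: {r}")
    cx, cy, cz = np.cos(r)
    sx, sy, sz = np.sin(r)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = rx @ ry @ rz
    return AffineTransform(m)


def scaling_matrix(s) -> AffineTransform:
    s = np.asarray(s, dtype=np.float64)
    if np.any(s < SCALE_RANGE[0] - 1e-12) or np.any(s > SCALE_RANGE[1] + 1e-12):
        raise RangeError(f"scale outside [0.5, 1.5]: {s}")
    return AffineTransform(np.diag([s[0], s[1], s[2], 1.0]))


def shearing_matrix(h) -> AffineTransform:
    h = np.asarray(h, dtype=np.float64)
    if np.any(np.abs(h) > SHEAR_BOUND + 1e-12):
        raise RangeError(f"shear outside [-pi, pi]: {h}")
    m = np.eye(4)
    m[0, 1] = h[0]  # h_xy
    m[0, 2] = h[1]  # h_xz
    m[1, 2] = h[2]  # h_yz
    return AffineTransform(m)


def compose_affine(p: GeometricParams, center=None) -> AffineTransform:
    """Ordered product A = T @ C @ R @ S @ H @ C^-1.

    ``center`` is the pivot for rotation/scale/shear, in normalized
    coordinates (defaults to the origin, i.e. the volume centre).
    """
    p.validate()
    tm = translation_matrix(p.t).matrix
    rm = rotation_matrix(p.r).matrix
    sm = scaling_matrix(p.s).matrix
    hm = shearing_matrix(p.h).matrix
    core = rm @ sm @ hm
    if center is not None:
        c = np.asarray(center, dtype=np.float64)
        cm = translation_matrix(c).matrix
        cm_inv = translation_matrix(-c).matrix
        core = cm @ core @ cm_inv
    return AffineTransform(tm @ core)


def decompose_affine(a: AffineTransform, center=None) -> GeometricParams:
    """Invert :func:`compose_affine`: recover [t, r, s, h] from a matrix.

    Uses the QR factorisation of the linear block (R orthogonal with
    ``det=+1``, upper-triangular factor with positive diagonal = S @ H).
    Euler angles are returned on the canonical branch ``|r_y| <= pi/2``; for
    rotations inside that branch the round trip is exact.
    """
    lin = a.linear
    q, u = np.linalg.qr(lin)
    sign = np.sign(np.diag(u))
    sign[sign == 0] = 1.0
    q = q * sign
    u = sign[:, None] * u
    s = np.diag(u).copy()
    h = np.array([u[0, 1] / s[0], u[0, 2] / s[0], u[1, 2] / s[1]])
    # Euler angles from R = R_x R_y R_z
    ry = np.arcsin(np.clip(q[0, 2], -1.0, 1.0))
    rz = np.arctan2(-q[0, 1], q[0, 0])
    rx = np.arctan2(-q[1, 2], q[2, 2])
    r = np.array([rx, ry, rz])
    trans = a.translation.copy()
    if center is not None:
        c = np.asarray(center, dtype=np.float64)
        trans = trans - (c - lin @ c)
    return GeometricParams(t=trans, r=r, s=s, h=h)


def constrain_params(raw) -> GeometricParams:
    """Smooth tanh squashing of 12 unconstrained scalars into the admissible box.

    t = 0.5 tanh(raw_t); r = pi tanh(raw_r); s = 1 + 0.5 tanh(raw_s);
    h = pi tanh(raw_h).  Differentiable, monotone per component, surjective
    onto the open constraint intervals.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != (12,):
        raise ValueError("raw parameter vector must have 12 entries")
    z = np.tanh(raw)
    return GeometricParams(t=0.5 * z[0:3], r=np.pi * z[3:6],
                           s=1.0 + 0.5 * z[6:9], h=np.pi * z[9:12])


# ---------------------------------------------------------------------------
# centre of mass & initialisation
# ---------------------------------------------------------------------------

def center_of_mass(volume: np.ndarray) -> np.ndarray:
    """Intensity-weighted centroid in voxel-index coordinates."""
    v = np.asarray(volume, dtype=np.float64)
    if np.any(v < 0):
        raise ValueError("centre of mass requires a non-negative image")
    total = v.sum()
    if total == 0:
        raise DegenerateImageError("image has zero total intensity")
    grids = np.meshgrid(*[np.arange(n) for n in v.shape], indexing="ij")
    return np.array([(g * v).sum() / total for g in grids])


def voxel_to_normalized(coords, shape) -> np.ndarray:
    """Map voxel-index coordinates to the normalized [-1, 1] frame."""
    coords = np.asarray(coords, dtype=np.float64)
    scale = np.array([(n - 1) / 2.0 for n in shape])
    return coords / scale - 1.0


def normalized_to_voxel(coords, shape) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.float64)
    scale = np.array([(n - 1) / 2.0 for n in shape])
    return (coords + 1.0) * scale


def com_align(fixed: np.ndarray, moving: np.ndarray) -> AffineTransform:
    """Pure translation mapping the moving image's centre of mass onto the
    fixed image's, as a pull/sampling transform in the normalized frame."""
    cf = voxel_to_normalized(center_of_mass(fixed), fixed.shape)
    cm = voxel_to_normalized(center_of_mass(moving), moving.shape)
    # sampling transform: fixed-frame point x reads moving at x + (cm - cf)
    return translation_matrix(cm - cf)


def accumulate(stage_transforms: list[AffineTransform]) -> AffineTransform:
    """Collapse an ordered list of stage transforms (stage 1 first) into one.

    In the pull convention, warping by ``A1`` then ``A2`` samples
    ``M(A1 @ A2 @ x)``; the single equivalent sampling matrix is the
    left-to-right product.  Warping the *original* moving image once by the
    result is the defined semantics (no repeated resampling).
    """
    if not stage_transforms:
        raise ValueError("accumulate requires a non-empty list of transforms")
    conv = stage_transforms[0].convention
    m = np.eye(4)
    for a in stage_transforms:
        if a.convention != conv:
            raise ValueError("all stage transforms must share one convention")
        m = m @ a.matrix
    return AffineTransform(m, conv)


# ---------------------------------------------------------------------------
# differentiable path (used by the network during training)
# ---------------------------------------------------------------------------

def constrain_params_t(raw: Tensor) -> Tensor:
    """Differentiable version of :func:`constrain_params`; returns the 12
    constrained scalars in [t, r, s, h] order."""
    z = raw.tanh()
    t = 0.5 * z[0:3]
    r = np.pi * z[3:6]
    s = 1.0 + 0.5 * z[6:9]
    h = np.pi * z[9:12]
    return _tensor.concat([t, r, s, h], axis=0)


def compose_affine_t(params: Tensor, center=None) -> Tensor:
    """Differentiable :func:`compose_affine` from a constrained 12-vector."""
    t, r, s, h = params[0:3], params[3:6], params[6:9], params[9:12]
    zero = Tensor(0.0)
    one = Tensor(1.0)

    cx, cy, cz = r[0].cos(), r[1].cos(), r[2].cos()
    sx, sy, sz = r[0].sin(), r[1].sin(), r[2].sin()
    rx = _tensor.stack([_tensor.stack([one, zero, zero]),
                        _tensor.stack([zero, cx, -sx]),
                        _tensor.stack([zero, sx, cx])])
    ry = _tensor.stack([_tensor.stack([cy, zero, sy]),
                        _tensor.stack([zero, one, zero]),
                        _tensor.stack([-sy, zero, cy])])
    rz = _tensor.stack([_tensor.stack([cz, -sz, zero]),
                        _tensor.stack([sz, cz, zero]),
                        _tensor.stack([zero, zero, one])])
    sm = _tensor.stack([_tensor.stack([s[0], zero, zero]),
                        _tensor.stack([zero, s[1], zero]),
                        _tensor.stack([zero, zero, s[2]])])
    hm = _tensor.stack([_tensor.stack([one, h[0], h[1]]),
                        _tensor.stack([zero, one, h[2]]),
                        _tensor.stack([zero, zero, one])])
    lin = rx @ ry @ rz @ sm @ hm

    if center is not None:
        c = np.asarray(center, dtype=np.float64)
        # conjugation by the pivot: x -> L (x - c) + c, as translation column
        shift = (Tensor(c) - lin @ Tensor(c)) + t
    else:
        shift = t

    top = _tensor.concat([lin, shift.reshape(3, 1)], axis=1)
    bottom = Tensor(np.array([[0.0, 0.0, 0.0, 1.0]]))
    return _tensor.concat([top, bottom], axis=0)
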