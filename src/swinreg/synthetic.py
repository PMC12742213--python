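"""Synthetic brain-like phantoms for training and validating registration.

Real rodent cohorts cannot ship with the package, so the generator emulates
the features the method actually exercises: a single-channel intensity volume
with an ellipsoidal "brain" containing nested labelled structures (cortical
shell, interior tissue, deep core, asymmetric blobs), smooth intensity
gradients, per-subject jitter of structure positions and sizes, seeded affine
misalignments inside the admissible parameter ranges, and additive Gaussian
noise.  The asymmetric blob layout makes rotations identifiable.

Pairs are built by warping the phantom with the *inverse* of a sampled
ground-truth transform, so the forward (sampling) transform the network must
output is exactly the sampled one — recovery is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (AffineTransform, GeometricParams, center_of_mass,
                       compose_affine, voxel_to_normalized,
                       TRANSLATION_BOUND, ROTATION_BOUND, SHEAR_BOUND, SCALE_RANGE)
from .warp import warp_volume

# Blob template centres (relative to the brain centre, units of the brain
# semi-axes) — deliberately asymmetric so no rotation maps the set onto itself.
_BLOB_TEMPLATES = [
    (0.38, 0.22, 0.15), (-0.30, 0.38, -0.22), (0.15, -0.42, 0.28),
    (-0.42, -0.25, 0.10), (0.30, -0.10, -0.38), (0.05, 0.45, 0.32),
    (-0.15, 0.12, 0.44), (0.45, 0.05, -0.15), (-0.05, -0.30, -0.40),
    (0.22, 0.30, 0.40),
]
_BLOB_RADIUS = 0.16           # fraction of the brain semi-axes
_BLOB_INTENSITIES = (0.92, 0.28, 0.85, 0.35, 0.78, 0.22, 0.95, 0.40, 0.70, 0.30)


@dataclass
class Phantom:
    volume: np.ndarray            # intensities in [0, 1]
    labels: np.ndarray            # integer structures, background 0
    seed: int
    n_structures: int


@dataclass
class AffineRanges:
    """Uniform sampling half-widths for misalignment parameters.

    Defaults are the well-posed test ranges (milder than the hard constraint
    bounds); ``full()`` gives the full admissible box."""

    rotation: float = 0.3         # radians, per axis
    translation: float = 0.15     # fraction of half-extent, per axis
    scale: tuple = (0.9, 1.1)
    shear: float = 0.1

    def __post_init__(self):
        if (self.rotation > ROTATION_BOUND or self.translation > TRANSLATION_BOUND
                or self.shear > SHEAR_BOUND
                or self.scale[0] < SCALE_RANGE[0] or self.scale[1] > SCALE_RANGE[1]):
            raise ValueError("sampling ranges exceed the admissible parameter box")

    @classmethod
    def full(cls) -> "AffineRanges":
        return cls(rotation=np.pi, translation=0.5, scale=SCALE_RANGE, shear=np.pi)

    @classmethod
    def identity(cls) -> "AffineRanges":
        return cls(rotation=0.0, translation=0.0, scale=(1.0, 1.0), shear=0.0)


def _normalized_coords(shape):
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(seed: int, shape=(96, 96, 48), n_structures: int = 8) -> Phantom:
    """Deterministic per-seed brain-like phantom with labelled substructures."""
    shape = tuple(int(n) for n in shape)
    if any(n < 32 for n in shape):
        raise ValueError("phantom shape must be at least 32 per axis")
    if n_structures < 2:
        raise ValueError("need at least 2 structures")
    max_k = 3 + len(_BLOB_TEMPLATES)
    if n_structures > max_k:
        raise ValueError(f"cannot place {n_structures} structures without overlap "
                         f"(maximum {max_k})")
    rng = np.random.default_rng(seed)
    xg, yg, zg = _normalized_coords(shape)

    # Per-subject anatomical jitter is sub-voxel in scale, emulating the high
    # within-strain homogeneity of a laboratory rodent cohort (whose members
    # are affinely registrable to a common atlas with high overlap).
    centre = rng.uniform(-0.01, 0.01, size=3)
    semi = np.array([0.72, 0.66, 0.62]) * rng.uniform(0.98, 1.02, size=3)
    rho = (((xg - centre[0]) / semi[0]) ** 2 + ((yg - centre[1]) / semi[1]) ** 2
           + ((zg - centre[2]) / semi[2]) ** 2)
    brain = rho <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    volume = np.zeros(shape)

    # structure 1: cortical shell; 2: interior tissue; 3: deep core; 4+: blobs
    shell = brain & (rho > 0.62)
    interior = rho <= 0.62
    volume[interior] = 0.50
    volume[shell] = 0.75
    labels[shell] = 1
    if n_structures >= 2:
        labels[interior] = 2

    if n_structures >= 3:
        core_c = centre + np.array([0.10, 0.05, -0.04]) + rng.uniform(-0.008, 0.008, 3)
        core_semi = semi * 0.30 * rng.uniform(0.97, 1.03)
        core = (((xg - core_c[0]) / core_semi[0]) ** 2
                + ((yg - core_c[1]) / core_semi[1]) ** 2
                + ((zg - core_c[2]) / core_semi[2]) ** 2) <= 1.0
        labels[core] = 3
        volume[core] = 0.60

    placed = []
    for k in range(n_structures - 3):
        rel = np.array(_BLOB_TEMPLATES[k]) + rng.uniform(-0.008, 0.008, 3)
        c = centre + rel * semi
        r = semi * _BLOB_RADIUS * rng.uniform(0.97, 1.03)
        for pc, pr in placed:
            if np.linalg.norm((c - pc) / (r + pr)) < 1.0:
                raise ValueError("structure placement overlap; reduce n_structures")
        placed.append((c, r))
        blob = (((xg - c[0]) / r[0]) ** 2 + ((yg - c[1]) / r[1]) ** 2
                + ((zg - c[2]) / r[2]) ** 2) <= 1.0
        labels[blob] = 4 + k
        volume[blob] = _BLOB_INTENSITIES[k]

    # smooth intensity gradient and light blurring
    phase = rng.uniform(0, 2 * np.pi, size=2)
    volume += 0.05 * np.sin(1.5 * xg + phase[0]) * np.cos(1.2 * yg + phase[1]) * brain
    volume = ndimage.gaussian_filter(volume, sigma=1.0)
    vmin, vmax = volume.min(), volume.max()
    volume = (volume - vmin) / (vmax - vmin)

    for k in range(1, n_structures + 1):
        if not np.any(labels == k):
            raise ValueError(f"structure {k} is empty at shape {shape}")
    return Phantom(volume=volume, labels=labels, seed=int(seed),
                   n_structures=n_structures)


def sample_affine_params(seed_or_rng, ranges: AffineRanges | None = None) -> GeometricParams:
    """Uniform per-component sampling inside ``ranges`` (seeded)."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    ranges = ranges or AffineRanges()
    return GeometricParams(
        t=rng.uniform(-ranges.translation, ranges.translation, 3),
        r=rng.uniform(-ranges.rotation, ranges.rotation, 3),
        s=rng.uniform(ranges.scale[0], ranges.scale[1], 3),
        h=rng.uniform(-ranges.shear, ranges.shear, 3),
    )


@dataclass
class RegistrationPair:
    fixed: np.ndarray
    fixed_labels: np.ndarray
    moving: np.ndarray
    moving_labels: np.ndarray
    params: GeometricParams          # ground truth (sampling convention)
    transform: AffineTransform       # ground-truth sampling transform
    noise_sd: float = 0.0


def make_pair(phantom: Phantom, params: GeometricParams, noise_sd: float = 0.0,
              rng: np.random.Generator | None = None,
              fixed: Phantom | None = None) -> RegistrationPair:
    """Build a (fixed, moving) pair with known ground truth.

    The moving image is the phantom warped by the *inverse* of the
    ground-truth sampling transform (plus optional Gaussian noise), so that
    warping the moving image by the ground-truth transform recovers the
    phantom.  ``fixed`` defaults to the phantom itself; passing a separate
    (atlas) phantom yields an inter-subject pair.
    """
    params.validate()
    fixed = fixed or phantom
    pivot = voxel_to_normalized(center_of_mass(phantom.volume), phantom.volume.shape)
    a_gt = compose_affine(params, center=pivot)
    inv = a_gt.inverse()
    moving = warp_volume(phantom.volume, inv)
    moving_labels = warp_volume(phantom.labels, inv, interpolation="nearest")
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        moving = np.clip(moving + rng.normal(0.0, noise_sd, moving.shape), 0.0, 1.0)
    return RegistrationPair(
        fixed=fixed.volume, fixed_labels=fixed.labels,
        moving=moving, moving_labels=moving_labels,
        params=params, transform=a_gt, noise_sd=noise_sd,
    )


@dataclass
class Cohort:
    atlas: Phantom
    pairs: list
    manifest: dict


def make_cohort(seed: int, n_pairs: int, shape=(96, 96, 48), n_structures: int = 8,
                ranges: AffineRanges | None = None, noise_sd: float = 0.0,
                inter_subject: bool = True) -> Cohort:
    """Seeded cohort: one atlas phantom plus misaligned subject pairs.

    With ``inter_subject`` each moving image derives from its own jittered
    phantom (anatomy differs from the atlas, as across real subjects);
    otherwise all pairs reuse the atlas anatomy.
    """
    ranges = ranges or AffineRanges()
    atlas = generate_phantom(seed, shape=shape, n_structures=n_structures)
    pairs = []
    manifest = {"seed": int(seed), "shape": list(shape), "n_structures": n_structures,
                "noise_sd": noise_sd, "inter_subject": inter_subject, "pairs": []}
    for i in range(n_pairs):
        subj_seed = seed + 1 + i
        subject = (generate_phantom(subj_seed, shape=shape, n_structures=n_structures)
                   if inter_subject else atlas)
        rng = np.random.default_rng(subj_seed * 7919 + 13)
        params = sample_affine_params(rng, ranges)
        pair = make_pair(subject, params, noise_sd=noise_sd, rng=rng, fixed=atlas)
        pairs.append(pair)
        manifest["pairs"].append({"subject_seed": subj_seed,
                                  "params": params.to_dict()})
    return Cohort(atlas=atlas, pairs=pairs, manifest=manifest)
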