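"""Multi-stage affine registration network.

Three stages operate on an image pyramid (scales 0.25, 0.5, 1.0).  Each stage
linearly embeds non-overlapping patches of the fixed image and the current
warped moving image (window 2/4/8 per stage, so raw patch vectors of length
8/64/512), fuses the two token sets, runs shifted-window multi-head
self-attention block pairs, a dilated convolutional block (two 3x3x3
convolutions with dilation 1 and 2, batch-norm and ReLU, receptive field
7x7x7), and regresses 12 geometric parameters with a Tanh MLP head.  Stage
transforms are accumulated and applied to the *original* moving image before
the next stage, so coarse stages remove gross misalignment and later stages
refine it; the moving image is only ever resampled once per stage from the
original data.

The head's final layer is zero-initialised, so an untrained network outputs
the identity transform (plus the optional centre-of-mass initialisation) and
training starts from an exact identity alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np

from . import _tensor, nn
from ._tensor import Tensor
from .geometry import (AffineTransform, GeometricParams, center_of_mass,
                       com_align, compose_affine_t, constrain_params,
                       constrain_params_t, voxel_to_normalized)
from .warp import downsample_half_t, warp_volume_t

_NEG_INF = -1e9


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``patch_windows`` are the per-stage patch-embedding window edges (2, 4, 8
    — raw patch vectors 8/64/512); the same per-stage window is used for
    attention (token grids are padded to window multiples).  ``depths`` counts
    swin block *pairs* per stage; between consecutive pairs a 2x2x2 patch
    merge halves the token grid and doubles the width.
    """

    embed_dim: int = 64
    depths: tuple = (1, 2, 2)
    patch_windows: tuple = (2, 4, 8)
    heads: int = 2
    mlp_ratio: float = 4.0
    levels: int = 3
    use_com_init: bool = True

    def __post_init__(self):
        self.depths = tuple(self.depths)
        self.patch_windows = tuple(self.patch_windows)
        if len(self.depths) != self.levels or len(self.patch_windows) != self.levels:
            raise ValueError("depths and patch_windows must have one entry per stage")
        if self.embed_dim % self.heads:
            raise ValueError("heads must divide embed_dim")

    @classmethod
    def tiny(cls) -> "NetworkConfig":
        """CPU-friendly preset used by the desk-scale experiments and tests."""
        return cls(embed_dim=16, depths=(1, 1, 1))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        return cls(**json.loads(text))


@dataclass
class TokenGrid:
    """A token sequence with its attached 3-D grid bookkeeping."""

    tokens: Tensor  # (N, C)
    grid: tuple     # (h, w, d) with h*w*d == N

    def __post_init__(self):
        n = int(np.prod(self.grid))
        if self.tokens.shape[0] != n:
            raise ValueError(f"token count {self.tokens.shape[0]} != grid {self.grid}")

    @property
    def width(self) -> int:
        return self.tokens.shape[1]


@dataclass
class StageOutput:
    raw: np.ndarray              # unconstrained 12-vector from the head
    params: GeometricParams      # after tanh constraint
    transform: AffineTransform   # this stage's matrix (normalized frame)


# ---------------------------------------------------------------------------
# pyramid
# ---------------------------------------------------------------------------

def build_pyramid(volume: np.ndarray, levels: int) -> list[np.ndarray]:
    """Trilinear pyramid; level i (1-based) has scale 0.5**(levels-i), the
    last level being the input itself.  Built by repeated halving so coarse
    levels are progressively smoothed."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    volume = np.asarray(volume, dtype=np.float64)
    factor = 2 ** (levels - 1)
    if any(n % factor or n // factor < 1 for n in volume.shape):
        raise ValueError(f"shape {volume.shape} not divisible into {levels} pyramid levels")
    pyr = [volume]
    with _tensor.no_grad():
        for _ in range(levels - 1):
            pyr.append(downsample_half_t(Tensor(pyr[-1])).data)
    return pyr[::-1]


# ---------------------------------------------------------------------------
# window partition helpers
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def relative_position_index(window: int) -> np.ndarray:
    """(V, V) flat indices into a (2w-1)^3 relative-offset table."""
    w = window
    coords = np.stack(np.meshgrid(*[np.arange(w)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
    rel = coords[:, None, :] - coords[None, :, :] + (w - 1)
    return (rel[..., 0] * (2 * w - 1) + rel[..., 1]) * (2 * w - 1) + rel[..., 2]


@lru_cache(maxsize=None)
def _shift_mask(padded_grid: tuple, window: int, shift: int) -> np.ndarray:
    """Additive attention mask for shifted windows (standard region-id trick)."""
    # segment ids are laid out directly in the rolled coordinate frame: the
    # tail [n-shift, n) holds the tokens wrapped around by the cyclic shift
    ids = np.zeros(padded_grid)
    cnt = 0
    segs = []
    for n in padded_grid:
        segs.append([slice(0, n - window), slice(n - window, n - shift), slice(n - shift, n)])
    for sx in segs[0]:
        for sy in segs[1]:
            for sz in segs[2]:
                ids[sx, sy, sz] = cnt
                cnt += 1
    n_axis = [n // window for n in padded_grid]
    ids = ids.reshape(n_axis[0], window, n_axis[1], window, n_axis[2], window)
    ids = ids.transpose(0, 2, 4, 1, 3, 5).reshape(-1, window ** 3)
    mask = np.where(ids[:, :, None] != ids[:, None, :], _NEG_INF, 0.0)
    return mask


def _partition(tg: TokenGrid, window: int, shift: int):
    """Tokens -> (nWin, V, C) windows (+ mask or None, + reverse closure)."""
    gh, gw, gd = tg.grid
    c = tg.width
    pad = [(-n) % window for n in tg.grid]
    x = tg.tokens.reshape(gh, gw, gd, c)
    if any(pad):
        x = x.pad(((0, pad[0]), (0, pad[1]), (0, pad[2]), (0, 0)))
    pg = (gh + pad[0], gw + pad[1], gd + pad[2])
    if shift:
        x = x.roll((-shift,) * 3, axes=(0, 1, 2))
    na = [n // window for n in pg]
    x = x.reshape(na[0], window, na[1], window, na[2], window, c)
    x = x.transpose((0, 2, 4, 1, 3, 5, 6)).reshape(-1, window ** 3, c)
    mask = _shift_mask(pg, window, shift) if shift else None

    def reverse(wins: Tensor) -> TokenGrid:
        y = wins.reshape(na[0], na[1], na[2], window, window, window, c)
        y = y.transpose((0, 3, 1, 4, 2, 5, 6)).reshape(pg[0], pg[1], pg[2], c)
        if shift:
            y = y.roll((shift,) * 3, axes=(0, 1, 2))
        y = y[:gh, :gw, :gd, :]
        return TokenGrid(y.reshape(gh * gw * gd, c), tg.grid)

    return x, mask, reverse


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class PatchEmbed(nn.Module):
    """Non-overlapping window flattening + learned linear projection to C,
    plus a learned embedding of each patch's normalized centre coordinate
    (tokens must carry absolute position for pose regression to be possible
    after mean pooling; resolution-independent by construction)."""

    def __init__(self, window: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.window = window
        self.proj = nn.Linear(window ** 3, dim, rng)
        self.pos = nn.Linear(3, dim, rng)
        # Informative initialisation: position features start at a scale
        # comparable to the content features, channel 0 of the projection is
        # seeded with the patch mean and channels 1-3 of the position map with
        # the raw coordinates, so attention can form content-selective
        # normalized spatial moments (the sufficient statistics of an affine
        # misalignment) from the first optimisation step.
        self.pos.weight.data *= 4.0
        self.proj.weight.data[:, 0] = 1.0 / window ** 3
        self.pos.weight.data[:, 1:4] = np.eye(3)

    def _patch_centers(self, grid: tuple) -> np.ndarray:
        axes = [(np.arange(n) + 0.5) / n * 2.0 - 1.0 for n in grid]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def __call__(self, volume) -> TokenGrid:
        v = volume if isinstance(volume, Tensor) else Tensor(np.asarray(volume, dtype=np.float64))
        w = self.window
        pad = [(-n) % w for n in v.shape]
        if any(pad):
            v = v.pad(tuple((0, p) for p in pad))
        nx, ny, nz = (n // w for n in v.shape)
        x = v.reshape(nx, w, ny, w, nz, w)
        x = x.transpose((0, 2, 4, 1, 3, 5)).reshape(nx * ny * nz, w ** 3)
        tokens = self.proj(x) + self.pos(Tensor(self._patch_centers((nx, ny, nz))))
        return TokenGrid(tokens, (nx, ny, nz))


class FusePair(nn.Module):
    """Concatenate fixed/moving token features and project back to C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(2 * dim, dim, rng)

    def __call__(self, zf: TokenGrid, zm: TokenGrid) -> TokenGrid:
        if zf.grid != zm.grid or zf.width != zm.width:
            raise ValueError("fixed/moving token grids must match")
        z = _tensor.concat([zf.tokens, zm.tokens], axis=-1)
        return TokenGrid(self.proj(z), zf.grid)


class WindowAttention(nn.Module):
    """Multi-head self-attention within (optionally shifted) local windows,
    with a learned relative-position bias per head."""

    def __init__(self, dim: int, window: int, heads: int, rng: np.random.Generator,
                 shifted: bool = False):
        super().__init__()
        if dim % heads:
            raise ValueError("heads must divide the feature width")
        self.dim = dim
        self.window = window
        self.heads = heads
        self.shifted = shifted
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.bias_table = nn.Parameter(np.zeros(((2 * window - 1) ** 3, heads)))

    def __call__(self, tg: TokenGrid) -> TokenGrid:
        w, hds, c = self.window, self.heads, self.dim
        shift = w // 2 if self.shifted else 0
        wins, mask, reverse = _partition(tg, w, shift)
        n_win, v = wins.shape[0], wins.shape[1]
        dh = c // hds

        qkv = self.qkv(wins)  # (nW, V, 3C)
        qkv = qkv.reshape(n_win, v, 3, hds, dh).transpose((2, 0, 3, 1, 4))
        q, k, vv = qkv[0], qkv[1], qkv[2]  # (nW, H, V, Dh)

        attn = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        idx = relative_position_index(w)
        bias = self.bias_table[idx.ravel()].reshape(v, v, hds).transpose((2, 0, 1))
        attn = attn + bias.reshape(1, hds, v, v)
        if mask is not None:
            attn = attn + mask[:, None, :, :]
        attn = attn.softmax(axis=-1)
        out = attn @ vv  # (nW, H, V, Dh)
        out = out.transpose((0, 2, 1, 3)).reshape(n_win, v, c)
        out = self.proj(out)
        return reverse(out)


class SwinBlockPair(nn.Module):
    """Two consecutive residual attention blocks: regular then shifted windows,
    each followed by a LayerNorm+MLP residual sub-block."""

    def __init__(self, dim: int, window: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, window, heads, rng, shifted=False)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp1 = nn.MLP(dim, hidden, rng)
        self.norm3 = nn.LayerNorm(dim)
        self.shifted_attn = WindowAttention(dim, window, heads, rng, shifted=True)
        self.norm4 = nn.LayerNorm(dim)
        self.mlp2 = nn.MLP(dim, hidden, rng)

    def __call__(self, tg: TokenGrid) -> TokenGrid:
        x = tg.tokens
        x = x + self.attn(TokenGrid(self.norm1(x), tg.grid)).tokens
        x = x + self.mlp1(self.norm2(x))
        x = x + self.shifted_attn(TokenGrid(self.norm3(x), tg.grid)).tokens
        x = x + self.mlp2(self.norm4(x))
        return TokenGrid(x, tg.grid)


class PatchMerge(nn.Module):
    """2x2x2 neighbourhood merge: concatenate 8 neighbours (8C) and project to
    2C, halving the token grid per axis."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(8 * dim, 2 * dim, rng)

    def __call__(self, tg: TokenGrid) -> TokenGrid:
        gh, gw, gd = tg.grid
        if gh % 2 or gw % 2 or gd % 2:
            raise ValueError(f"patch merging requires an even grid, got {tg.grid}")
        c = tg.width
        x = tg.tokens.reshape(gh // 2, 2, gw // 2, 2, gd // 2, 2, c)
        x = x.transpose((0, 2, 4, 1, 3, 5, 6)).reshape(-1, 8 * c)
        return TokenGrid(self.proj(x), (gh // 2, gw // 2, gd // 2))


class DilatedConvBlock(nn.Module):
    """Tokens -> spatial map -> [conv3x3 d=1, BN, ReLU, conv3x3 d=2, BN, ReLU]
    -> tokens; spatial shape preserved, effective receptive field 7 per axis."""

    def __init__(self, dim: int, rng: np.random.Generator, dilations=(1, 2)):
        super().__init__()
        self.conv1 = nn.Conv3d(dim, dim, 3, rng, dilation=dilations[0])
        self.bn1 = nn.BatchNorm(dim)
        self.conv2 = nn.Conv3d(dim, dim, 3, rng, dilation=dilations[1])
        self.bn2 = nn.BatchNorm(dim)

    def __call__(self, tg: TokenGrid) -> TokenGrid:
        gh, gw, gd = tg.grid
        x = tg.tokens.reshape(gh, gw, gd, tg.width)
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        return TokenGrid(x.reshape(gh * gw * gd, tg.width), tg.grid)


class AffineHead(nn.Module):
    """Mean-pooled tokens -> linear -> Tanh -> linear -> raw 12-vector.

    The final layer is zero-initialised so the untrained head predicts the
    identity transform."""

    def __init__(self, dim: int, rng: np.random.Generator, hidden: int | None = None):
        super().__init__()
        hidden = hidden or 4 * dim
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, 12, rng, zero_init=True)

    def __call__(self, tg: TokenGrid) -> Tensor:
        pooled = tg.tokens.mean(axis=0)
        return self.fc2(self.fc1(pooled).tanh())


class Stage(nn.Module):
    """One resolution level: embed both images, fuse, attend, convolve, regress."""

    def __init__(self, cfg: NetworkConfig, stage_idx: int, rng: np.random.Generator):
        super().__init__()
        window = cfg.patch_windows[stage_idx]
        dim = cfg.embed_dim
        self.embed_fixed = PatchEmbed(window, dim, rng)
        self.embed_moving = PatchEmbed(window, dim, rng)
        self.fuse = FusePair(dim, rng)
        self.pairs = []
        self.merges = []
        for k in range(cfg.depths[stage_idx]):
            self.pairs.append(SwinBlockPair(dim, window, cfg.heads, cfg.mlp_ratio, rng))
            if k < cfg.depths[stage_idx] - 1:
                self.merges.append(PatchMerge(dim, rng))
                dim *= 2
        self.dconv = DilatedConvBlock(dim, rng)
        self.head = AffineHead(dim, rng)

    def __call__(self, fixed_level, moving_level) -> Tensor:
        zf = self.embed_fixed(fixed_level)
        zm = self.embed_moving(moving_level)
        z = self.fuse(zf, zm)
        for k, pair in enumerate(self.pairs):
            z = pair(z)
            if k < len(self.merges):
                z = self.merges[k](z)
        z = self.dconv(z)
        return self.head(z)


@dataclass
class ForwardResult:
    transform: AffineTransform        # accumulated sampling transform
    transform_t: Tensor               # same, on the autodiff tape
    stages: list                      # per-stage StageOutput
    stage_params_t: list              # per-stage constrained 12-vectors (Tensors)


class MultiStageAffineNetwork(nn.Module):
    """The full cascade.  ``forward`` runs on numpy volumes (values in [0, 1],
    identical shapes) and returns the accumulated affine sampling transform
    together with per-stage outputs; deterministic given fixed weights."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(seed)
        self.stages = [Stage(self.config, i, rng) for i in range(self.config.levels)]

    # -- inference ------------------------------------------------------------
    def forward(self, fixed: np.ndarray, moving: np.ndarray) -> ForwardResult:
        fixed = np.asarray(fixed, dtype=np.float64)
        moving = np.asarray(moving, dtype=np.float64)
        if fixed.shape != moving.shape:
            raise ValueError(f"shape mismatch: fixed {fixed.shape} vs moving {moving.shape}")
        levels = self.config.levels
        f_pyr = build_pyramid(fixed, levels)

        if self.config.use_com_init:
            acc = Tensor(com_align(fixed, moving).matrix)
        else:
            acc = Tensor(np.eye(4))

        stage_outputs: list[StageOutput] = []
        stage_params_t: list[Tensor] = []
        for i, stage in enumerate(self.stages):
            warped = warp_volume_t(moving, acc, moving.shape)
            m_i = warped
            for _ in range(levels - 1 - i):
                m_i = downsample_half_t(m_i)
            raw = stage(f_pyr[i], m_i)
            params_t = constrain_params_t(raw)
            center = self._pivot(warped.data)
            a_i = compose_affine_t(params_t, center)
            acc = acc @ a_i
            stage_outputs.append(StageOutput(
                raw=raw.data.copy(),
                params=GeometricParams.from_vector(params_t.data),
                transform=AffineTransform(a_i.data.copy()),
            ))
            stage_params_t.append(params_t)
        return ForwardResult(
            transform=AffineTransform(acc.data.copy()),
            transform_t=acc,
            stages=stage_outputs,
            stage_params_t=stage_params_t,
        )

    @staticmethod
    def _pivot(volume: np.ndarray) -> np.ndarray:
        """Rotation/scale/shear pivot: the warped moving image's centre of mass
        (normalized coords); falls back to the origin for empty images."""
        v = np.clip(volume, 0.0, None)
        if v.sum() <= 0:
            return np.zeros(3)
        return voxel_to_normalized(center_of_mass(v), v.shape)

    def register(self, fixed: np.ndarray, moving: np.ndarray) -> ForwardResult:
        """Inference without building the autodiff graph."""
        self.eval()
        with _tensor.no_grad():
            return self.forward(fixed, moving)

    # -- checkpointing --------------------------------------------------------
    def save(self, weight_path, sidecar_path=None) -> None:
        nn.save_weights(self, weight_path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                fh.write(self.config.to_json())

    @classmethod
    def from_checkpoint(cls, weight_path, sidecar_path) -> "MultiStageAffineNetwork":
        with open(sidecar_path) as fh:
            cfg = NetworkConfig.from_json(fh.read())
        net = cls(cfg)
        nn.load_weights(net, weight_path)
        return net
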