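"""Architecture components: embedding, fusion, windowed attention (against a
dense masked-attention oracle), merging, dilated convolutions, heads and the
full cascade."""

import numpy as np
import pytest

from swinreg import nn
from swinreg._tensor import Tensor
from swinreg.geometry import com_align
from swinreg.network import (AffineHead, DilatedConvBlock, FusePair,
                             MultiStageAffineNetwork, NetworkConfig, PatchEmbed,
                             PatchMerge, Stage, SwinBlockPair, TokenGrid,
                             WindowAttention, build_pyramid,
                             relative_position_index)


def make_grid(rng, grid, dim):
    n = int(np.prod(grid))
    return TokenGrid(Tensor(rng.normal(size=(n, dim))), tuple(grid))


def zero_linears(module):
    for _, p in module.named_parameters():
        if not p.data.ndim or "gamma" in repr(p.data):
            continue
    for name, p in module.named_parameters():
        if name.endswith("weight") or name.endswith("bias"):
            p.data[...] = 0.0


class TestBuildPyramid:
    def test_single_level_is_input(self, smooth_volume):
        pyr = build_pyramid(smooth_volume, 1)
        assert len(pyr) == 1
        np.testing.assert_array_equal(pyr[0], smooth_volume)

    def test_three_level_shapes(self):
        v = np.zeros((96, 96, 48))
        pyr = build_pyramid(v, 3)
        assert [p.shape for p in pyr] == [(24, 24, 12), (48, 48, 24), (96, 96, 48)]

    def test_mean_intensity_preserved_on_smooth_phantom(self, smooth_volume):
        pyr = build_pyramid(smooth_volume, 3)
        for level in pyr:
            assert abs(level.mean() - smooth_volume.mean()) / smooth_volume.mean() < 0.05

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError):
            build_pyramid(np.zeros((30, 32, 32)), 3)


class TestPatchEmbed:
    @pytest.mark.parametrize("window,length", [(2, 8), (4, 64), (8, 512)])
    def test_flattened_patch_lengths(self, window, length, rng):
        embed = PatchEmbed(window, 16, rng)
        assert embed.proj.weight.shape[0] == length

    def test_single_window_volume_gives_one_token(self, rng):
        embed = PatchEmbed(2, 8, rng)
        out = embed(np.arange(8, dtype=float).reshape(2, 2, 2))
        assert out.grid == (1, 1, 1)
        assert out.tokens.shape == (1, 8)

    def test_identity_projection_recovers_flattened_patch(self, rng):
        embed = PatchEmbed(2, 8, rng)
        embed.proj.weight.data = np.eye(8)
        embed.proj.bias.data[...] = 0.0
        embed.pos.weight.data[...] = 0.0
        embed.pos.bias.data[...] = 0.0
        v = rng.normal(size=(2, 2, 2))
        out = embed(v)
        np.testing.assert_allclose(out.tokens.data[0],
                                   v.reshape(2, 2, 2).transpose(0, 1, 2).ravel())

    def test_pads_indivisible_volume(self, rng):
        embed = PatchEmbed(4, 8, rng)
        out = embed(rng.normal(size=(6, 8, 5)))
        assert out.grid == (2, 2, 2)


class TestFusePair:
    def test_zero_tokens_fuse_to_zero(self, rng):
        fuse = FusePair(8, rng)
        fuse.proj.bias.data[...] = 0.0
        z = TokenGrid(Tensor(np.zeros((4, 8))), (4, 1, 1))
        out = fuse(z, z)
        np.testing.assert_allclose(out.tokens.data, 0.0)
        assert out.grid == z.grid

    def test_swapping_inputs_changes_output(self, rng):
        fuse = FusePair(8, rng)
        a, b = make_grid(rng, (2, 2, 1), 8), make_grid(rng, (2, 2, 1), 8)
        out_ab = fuse(a, b).tokens.data
        out_ba = fuse(b, a).tokens.data
        assert not np.allclose(out_ab, out_ba)

    def test_shape_mismatch_rejected(self, rng):
        fuse = FusePair(8, rng)
        with pytest.raises(ValueError):
            fuse(make_grid(rng, (2, 2, 1), 8), make_grid(rng, (2, 1, 2), 8))


def dense_attention_oracle(attn: WindowAttention, tg: TokenGrid):
    """Brute-force reference: dense attention over all (padded-grid) tokens
    restricted by an explicit same-window rule, computed with the module's own
    weights via plain numpy loops.

    The shifted partition is defined geometrically: windows are offset by
    ``shift``, so two tokens may attend iff ``floor((p - shift)/w)`` matches
    on every axis (the first window is truncated; no cyclic wrap-around).
    In-window coordinates for the relative-position bias are
    ``(p - shift) mod w``.
    """
    w, heads, c = attn.window, attn.heads, attn.dim
    shift = w // 2 if attn.shifted else 0
    gh, gw, gd = tg.grid
    pg = tuple(n + ((-n) % w) for n in tg.grid)

    positions = [(i, j, k) for i in range(pg[0]) for j in range(pg[1])
                 for k in range(pg[2])]
    tok_index = {}
    for t, (i, j, k) in enumerate((i, j, k) for i in range(gh) for j in range(gw)
                                  for k in range(gd)):
        tok_index[(i, j, k)] = t

    x = np.zeros((len(positions), c))
    for idx, p in enumerate(positions):
        if p in tok_index:
            x[idx] = tg.tokens.data[tok_index[p]]

    def window_of(p):
        return tuple((ax - shift) // w for ax in p)   # floor division (negatives ok)

    def in_window(p):
        return tuple((ax - shift) % w for ax in p)

    qkv = x @ attn.qkv.weight.data + attn.qkv.bias.data
    q, kk, v = qkv[:, :c], qkv[:, c:2 * c], qkv[:, 2 * c:]
    dh = c // heads
    table = attn.bias_table.data
    out = np.zeros((len(positions), c))
    for a_idx, pa in enumerate(positions):
        allowed = [b_idx for b_idx, pb in enumerate(positions)
                   if window_of(pb) == window_of(pa)]
        for h in range(heads):
            qa = q[a_idx, h * dh:(h + 1) * dh]
            scores = []
            for b_idx in allowed:
                pb = positions[b_idx]
                kb = kk[b_idx, h * dh:(h + 1) * dh]
                rel = np.array(in_window(pa)) - np.array(in_window(pb)) + w - 1
                bias_idx = (rel[0] * (2 * w - 1) + rel[1]) * (2 * w - 1) + rel[2]
                scores.append(qa @ kb / np.sqrt(dh) + table[bias_idx, h])
            e = np.exp(scores - np.max(scores))
            prob = e / e.sum()
            for p_b, b_idx in zip(prob, allowed):
                out[a_idx, h * dh:(h + 1) * dh] += p_b * v[b_idx, h * dh:(h + 1) * dh]
    out = out @ attn.proj.weight.data + attn.proj.bias.data

    result = np.zeros((gh * gw * gd, c))
    for idx, p in enumerate(positions):
        if p in tok_index:
            result[tok_index[p]] = out[idx]
    return result


class TestWindowAttention:
    def test_single_token_windows_reduce_to_value_projection(self, rng):
        attn = WindowAttention(6, window=1, heads=1, rng=rng)
        tg = make_grid(rng, (2, 2, 2), 6)
        out = attn(tg)
        x = tg.tokens.data
        v = x @ attn.qkv.weight.data[:, 12:] + attn.qkv.bias.data[12:]
        expected = v @ attn.proj.weight.data + attn.proj.bias.data
        np.testing.assert_allclose(out.tokens.data, expected, atol=1e-12)

    def test_uniform_tokens_give_uniform_output(self, rng):
        attn = WindowAttention(8, window=2, heads=2, rng=rng)
        tok = np.tile(rng.normal(size=8), (8, 1))
        out = attn(TokenGrid(Tensor(tok), (2, 2, 2))).tokens.data
        np.testing.assert_allclose(out, np.tile(out[0], (8, 1)), atol=1e-10)

    @pytest.mark.parametrize("grid,shifted", [
        ((4, 4, 4), False), ((4, 4, 4), True),
        ((3, 5, 4), False), ((3, 5, 4), True),   # padding paths
        ((6, 6, 6), True),
    ])
    def test_matches_dense_masked_oracle(self, rng, grid, shifted):
        attn = WindowAttention(4, window=2, heads=2, rng=rng, shifted=shifted)
        attn.bias_table.data = rng.normal(size=attn.bias_table.shape) * 0.1
        tg = make_grid(rng, grid, 4)
        out = attn(tg).tokens.data
        oracle = dense_attention_oracle(attn, tg)
        assert np.abs(out - oracle).max() < 1e-5

    def test_heads_must_divide_width(self, rng):
        with pytest.raises(ValueError):
            WindowAttention(6, window=2, heads=4, rng=rng)


class TestSwinBlockPair:
    def test_zeroed_weights_give_identity(self, rng):
        pair = SwinBlockPair(8, window=2, heads=2, mlp_ratio=2, rng=rng)
        for name, p in pair.named_parameters():
            if name.endswith("weight") or name.endswith("bias") or "bias_table" in name:
                p.data[...] = 0.0
        tg = make_grid(rng, (2, 2, 2), 8)
        out = pair(tg)
        np.testing.assert_allclose(out.tokens.data, tg.tokens.data, atol=1e-12)

    def test_preserves_shape(self, rng):
        pair = SwinBlockPair(8, window=2, heads=2, mlp_ratio=2, rng=rng)
        tg = make_grid(rng, (4, 2, 2), 8)
        out = pair(tg)
        assert out.tokens.shape == tg.tokens.shape and out.grid == tg.grid

    def test_shift_matters_beyond_one_window(self, rng):
        pair = SwinBlockPair(8, window=2, heads=2, mlp_ratio=2, rng=rng)
        tg = make_grid(rng, (4, 4, 4), 8)
        out = pair(tg).tokens.data
        pair.shifted_attn.shifted = False   # ablate the shift
        out_noshift = pair(tg).tokens.data
        assert not np.allclose(out, out_noshift)


class TestPatchMerge:
    def test_eight_to_one_with_doubled_width(self, rng):
        merge = PatchMerge(8, rng)
        out = merge(make_grid(rng, (2, 2, 2), 8))
        assert out.grid == (1, 1, 1)
        assert out.tokens.shape == (1, 16)

    def test_token_count_divides_by_eight(self, rng):
        merge = PatchMerge(4, rng)
        out = merge(make_grid(rng, (4, 2, 6), 4))
        assert out.tokens.shape[0] == 4 * 2 * 6 // 8

    def test_merged_token_gathers_all_eight_parents(self, rng):
        c = 4
        merge = PatchMerge(c, rng)
        tg = make_grid(rng, (2, 2, 2), c)
        for slot in range(8):
            merge.proj.weight.data[...] = 0.0
            merge.proj.bias.data[...] = 0.0
            merge.proj.weight.data[slot * c, 0] = 1.0   # select parent `slot`, feature 0
            out = merge(tg).tokens.data
            # parent order is (dx, dy, dz) within the 2x2x2 neighbourhood
            dx, dy, dz = slot // 4, (slot // 2) % 2, slot % 2
            parent = tg.tokens.data.reshape(2, 2, 2, c)[dx, dy, dz]
            assert out[0, 0] == pytest.approx(parent[0])

    def test_odd_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            PatchMerge(4, rng)(make_grid(rng, (3, 2, 2), 4))


class TestDilatedConvBlock:
    def test_impulse_support_is_seven(self, rng):
        block = DilatedConvBlock(1, rng)
        block.conv1.weight.data[...] = 1.0
        block.conv2.weight.data[...] = 1.0
        block.conv1.bias.data[...] = 0.0
        block.conv2.bias.data[...] = 0.0
        block.eval()  # running stats (mean 0, var 1): normalisation is benign
        n = 15
        tokens = np.zeros((n ** 3, 1))
        tokens[(n ** 3) // 2] = 1.0
        out = block(TokenGrid(Tensor(tokens), (n, n, n))).tokens.data.reshape(n, n, n)
        support = np.where(out[:, n // 2, n // 2] > 0)[0]
        assert support.max() - support.min() + 1 == 7

    def test_zero_kernels_give_zero_output(self, rng):
        block = DilatedConvBlock(4, rng)
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        block.eval()
        out = block(make_grid(rng, (3, 3, 3), 4))
        np.testing.assert_allclose(out.tokens.data, 0.0)

    def test_token_count_preserved(self, rng):
        block = DilatedConvBlock(4, rng)
        tg = make_grid(rng, (4, 3, 2), 4)
        assert block(tg).tokens.shape == tg.tokens.shape


class TestAffineHead:
    def test_zero_final_layer_gives_zero_raw_vector(self, rng):
        head = AffineHead(8, rng)
        head.fc2.weight.data[...] = 0.0
        head.fc2.bias.data[...] = 0.0
        out = head(make_grid(rng, (2, 2, 2), 8))
        assert out.shape == (12,)
        np.testing.assert_allclose(out.data, 0.0)

    def test_default_init_is_near_zero(self, rng):
        out = AffineHead(8, rng)(make_grid(rng, (2, 2, 2), 8))
        assert np.abs(out.data).max() < 0.2

    def test_permutation_invariance(self, rng):
        head = AffineHead(8, rng)
        head.fc2.weight.data = rng.normal(size=head.fc2.weight.shape) * 0.1
        tg = make_grid(rng, (2, 2, 2), 8)
        out = head(tg).data
        perm = rng.permutation(8)
        tg_perm = TokenGrid(Tensor(tg.tokens.data[perm]), tg.grid)
        np.testing.assert_allclose(head(tg_perm).data, out, atol=1e-12)


class TestFullNetwork:
    @staticmethod
    def _zero_heads(net):
        for stage in net.stages:
            stage.head.fc2.weight.data[...] = 0.0
            stage.head.fc2.bias.data[...] = 0.0

    def test_zeroed_heads_output_com_alignment_exactly(self, phantom32):
        from swinreg.synthetic import make_pair, sample_affine_params
        net = MultiStageAffineNetwork(NetworkConfig.tiny(), seed=0)
        self._zero_heads(net)
        pair = make_pair(phantom32, sample_affine_params(3))
        result = net.register(pair.fixed, pair.moving)
        expected = com_align(pair.fixed, pair.moving).matrix
        np.testing.assert_allclose(result.transform.matrix, expected, atol=1e-12)
        assert len(result.stages) == 3

    def test_untrained_network_is_near_com_alignment(self, phantom32):
        from swinreg.synthetic import make_pair, sample_affine_params
        net = MultiStageAffineNetwork(NetworkConfig.tiny(), seed=0)
        pair = make_pair(phantom32, sample_affine_params(3))
        result = net.register(pair.fixed, pair.moving)
        expected = com_align(pair.fixed, pair.moving).matrix
        assert np.abs(result.transform.matrix - expected).max() < 0.2

    def test_self_registration_with_zeroed_heads_is_identity(self, phantom32):
        net = MultiStageAffineNetwork(NetworkConfig.tiny(), seed=0)
        self._zero_heads(net)
        result = net.register(phantom32.volume, phantom32.volume)
        np.testing.assert_allclose(result.transform.matrix, np.eye(4), atol=1e-10)

    def test_deterministic_given_weights(self, phantom32, tiny_network):
        from swinreg.synthetic import make_pair, sample_affine_params
        pair = make_pair(phantom32, sample_affine_params(3))
        a = tiny_network.register(pair.fixed, pair.moving).transform.matrix
        b = tiny_network.register(pair.fixed, pair.moving).transform.matrix
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_rejected(self, tiny_network):
        with pytest.raises(ValueError):
            tiny_network.forward(np.zeros((32, 32, 32)), np.zeros((32, 32, 16)))

    def test_checkpoint_round_trip(self, tmp_path, phantom32, rng):
        net = MultiStageAffineNetwork(NetworkConfig.tiny(), seed=1)
        # make stage outputs non-trivial so the check is meaningful
        for stage in net.stages:
            stage.head.fc2.weight.data = rng.normal(size=stage.head.fc2.weight.shape) * 0.01
        net.save(tmp_path / "w.npz", tmp_path / "cfg.json")
        restored = MultiStageAffineNetwork.from_checkpoint(tmp_path / "w.npz",
                                                           tmp_path / "cfg.json")
        a = net.register(phantom32.volume, np.roll(phantom32.volume, 2, axis=0))
        b = restored.register(phantom32.volume, np.roll(phantom32.volume, 2, axis=0))
        np.testing.assert_allclose(a.transform.matrix, b.transform.matrix, atol=1e-12)
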