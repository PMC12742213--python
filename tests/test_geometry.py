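"""Geometric transformation model: elementary matrices, composition,
constraints, centre of mass and stage accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swinreg import _tensor
from swinreg.geometry import (AffineTransform, DegenerateImageError,
                              GeometricParams, RangeError, accumulate,
                              center_of_mass, com_align, compose_affine,
                              compose_affine_t, constrain_params,
                              constrain_params_t, decompose_affine,
                              rotation_matrix, scaling_matrix, shearing_matrix,
                              translation_matrix, voxel_to_normalized)
from swinreg._tensor import Tensor
from swinreg.warp import warp_volume


def random_params(rng) -> GeometricParams:
    return GeometricParams(t=rng.uniform(-0.4, 0.4, 3),
                           r=rng.uniform(-2.5, 2.5, 3),
                           s=rng.uniform(0.6, 1.4, 3),
                           h=rng.uniform(-0.8, 0.8, 3))


class TestElementaryMatrices:
    def test_zero_translation_is_identity(self):
        np.testing.assert_allclose(translation_matrix((0, 0, 0)).matrix, np.eye(4))

    def test_translation_layout(self):
        m = translation_matrix((0.1, -0.2, 0.3)).matrix
        expected = np.eye(4)
        expected[:3, 3] = [0.1, -0.2, 0.3]
        np.testing.assert_allclose(m, expected)

    def test_translation_inverse_pair_cancels(self):
        a = translation_matrix((0.5, 0, 0))
        b = translation_matrix((-0.5, 0, 0))
        np.testing.assert_allclose(accumulate([a, b]).matrix, np.eye(4), atol=1e-15)

    def test_zero_rotation_is_identity(self):
        np.testing.assert_allclose(rotation_matrix((0, 0, 0)).matrix, np.eye(4))

    def test_quarter_turn_about_x(self):
        m = rotation_matrix((np.pi / 2, 0, 0)).matrix
        expected = np.array([[1, 0, 0, 0], [0, 0, -1, 0], [0, 1, 0, 0], [0, 0, 0, 1.0]])
        np.testing.assert_allclose(m, expected, atol=1e-15)

    @given(st.lists(st.floats(-np.pi, np.pi), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_rotation_block_is_orthonormal(self, r):
        q = rotation_matrix(r).linear
        np.testing.assert_allclose(q.T @ q, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(q), 1.0, atol=1e-10)

    def test_rotation_range_rejected(self):
        with pytest.raises(RangeError):
            rotation_matrix((3.5, 0, 0))

    def test_unit_scale_and_zero_shear_are_identity(self):
        np.testing.assert_allclose(scaling_matrix((1, 1, 1)).matrix, np.eye(4))
        np.testing.assert_allclose(shearing_matrix((0, 0, 0)).matrix, np.eye(4))

    def test_scaling_determinant(self, rng):
        s = rng.uniform(0.5, 1.5, 3)
        assert np.isclose(np.linalg.det(scaling_matrix(s).matrix), s.prod())

    def test_shear_layout(self):
        m = shearing_matrix((0.2, 0.3, 0.4)).matrix
        expected = np.eye(4)
        expected[0, 1], expected[0, 2], expected[1, 2] = 0.2, 0.3, 0.4
        np.testing.assert_allclose(m, expected)

    @pytest.mark.parametrize("fn,bad", [
        (scaling_matrix, (0.4, 1, 1)), (scaling_matrix, (1.6, 1, 1)),
        (shearing_matrix, (4.0, 0, 0)),
    ])
    def test_range_errors(self, fn, bad):
        with pytest.raises(RangeError):
            fn(bad)


class TestCompose:
    def test_identity_params_any_center(self, rng):
        p = GeometricParams.identity()
        for _ in range(3):
            c = rng.uniform(-0.5, 0.5, 3)
            np.testing.assert_allclose(compose_affine(p, c).matrix, np.eye(4), atol=1e-14)

    def test_pure_translation_ignores_center(self, rng):
        p = GeometricParams(t=(0.2, -0.1, 0.3), r=np.zeros(3), s=np.ones(3), h=np.zeros(3))
        m1 = compose_affine(p, center=None).matrix
        m2 = compose_affine(p, center=rng.uniform(-0.5, 0.5, 3)).matrix
        np.testing.assert_allclose(m1, m2, atol=1e-14)
        np.testing.assert_allclose(m1, translation_matrix(p.t).matrix)

    def test_matches_four_matrix_product(self, rng):
        for _ in range(5):
            p = random_params(rng)
            c = rng.uniform(-0.3, 0.3, 3)
            tm = translation_matrix(p.t).matrix
            cm = translation_matrix(c).matrix
            cm_inv = translation_matrix(-c).matrix
            brute = tm @ cm @ (rotation_matrix(p.r).matrix
                               @ scaling_matrix(p.s).matrix
                               @ shearing_matrix(p.h).matrix) @ cm_inv
            np.testing.assert_allclose(compose_affine(p, c).matrix, brute, atol=1e-12)

    def test_positive_determinant_for_in_range_params(self, rng):
        for _ in range(50):
            p = random_params(rng)
            assert np.linalg.det(compose_affine(p).linear) > 0

    def test_decompose_round_trip(self, rng):
        # Euler angles are unique only on the canonical branch |r_y| < pi/2
        for _ in range(10):
            p = random_params(rng)
            p.r = rng.uniform(-1.4, 1.4, 3)
            c = rng.uniform(-0.3, 0.3, 3)
            q = decompose_affine(compose_affine(p, c), c)
            np.testing.assert_allclose(q.as_vector(), p.as_vector(), atol=1e-9)

    def test_differentiable_compose_matches_numpy(self, rng):
        p = random_params(rng)
        c = rng.uniform(-0.3, 0.3, 3)
        m_t = compose_affine_t(Tensor(p.as_vector()), c)
        np.testing.assert_allclose(m_t.data, compose_affine(p, c).matrix, atol=1e-12)


class TestConstrainParams:
    def test_zero_raw_gives_identity(self):
        p = constrain_params(np.zeros(12))
        np.testing.assert_allclose(p.as_vector(), GeometricParams.identity().as_vector())

    def test_saturation_limits(self):
        hi = constrain_params(np.full(12, 50.0))
        lo = constrain_params(np.full(12, -50.0))
        np.testing.assert_allclose(hi.s, 1.5)
        np.testing.assert_allclose(lo.s, 0.5)
        np.testing.assert_allclose(hi.t, 0.5)
        np.testing.assert_allclose(hi.r, np.pi)

    def test_always_in_range(self, rng):
        raws = rng.normal(0, 10, size=(100_000, 12))
        z = np.tanh(raws)
        assert np.all(np.abs(0.5 * z[:, 0:3]) <= 0.5)
        for raw in raws[:200]:
            constrain_params(raw).validate()

    def test_monotone_per_component(self):
        grid = np.linspace(-3, 3, 101)
        for comp in range(12):
            raws = np.zeros((101, 12))
            raws[:, comp] = grid
            vals = np.array([constrain_params(r).as_vector()[comp] for r in raws])
            assert np.all(np.diff(vals) > 0)

    def test_differentiable_version_matches(self, rng):
        raw = rng.normal(size=12)
        np.testing.assert_allclose(constrain_params_t(Tensor(raw)).data,
                                   constrain_params(raw).as_vector(), atol=1e-14)


class TestCenterOfMass:
    def test_single_voxel(self):
        v = np.zeros((8, 9, 10))
        v[2, 5, 7] = 3.0
        np.testing.assert_allclose(center_of_mass(v), [2, 5, 7])

    def test_uniform_cube(self):
        v = np.ones((9, 9, 9))
        np.testing.assert_allclose(center_of_mass(v), [4, 4, 4])

    def test_matches_brute_force_loop(self, rng):
        v = rng.uniform(0, 1, size=(6, 5, 4))
        num = np.zeros(3)
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    num += np.array([i, j, k]) * v[i, j, k]
        np.testing.assert_allclose(center_of_mass(v), num / v.sum(), atol=1e-9)

    def test_degenerate_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            center_of_mass(np.zeros((4, 4, 4)))


@pytest.fixture
def compact_blob():
    """Compactly supported blob (zero background) so integer rolls shift the
    centre of mass exactly."""
    x, y, z = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
    r2 = (x - 14) ** 2 + (y - 16) ** 2 + (z - 18) ** 2
    v = np.exp(-r2 / 18.0)
    v[r2 > 49] = 0.0
    return v


class TestComAlign:
    def test_identical_images_give_identity(self, compact_blob):
        m = com_align(compact_blob, compact_blob).matrix
        np.testing.assert_allclose(m, np.eye(4), atol=1e-12)

    def test_shift_and_recover(self, compact_blob):
        shifted = np.roll(compact_blob, 3, axis=0)
        a = com_align(compact_blob, shifted)
        # sampling offset along x equals +3 voxels in normalized units
        n = compact_blob.shape[0]
        np.testing.assert_allclose(a.matrix[0, 3], 2 * 3 / (n - 1), atol=1e-3)

    def test_post_condition_alignment(self, compact_blob):
        shifted = np.roll(compact_blob, (3, -2, 1), axis=(0, 1, 2))
        a = com_align(compact_blob, shifted)
        warped = warp_volume(shifted, a)
        delta = center_of_mass(compact_blob) - center_of_mass(warped)
        assert np.all(np.abs(delta) < 0.5)


class TestAccumulate:
    def test_identity_list(self):
        np.testing.assert_allclose(accumulate([AffineTransform.identity()]).matrix, np.eye(4))

    def test_inverse_pair(self, rng):
        a = compose_affine(random_params(rng))
        np.testing.assert_allclose(accumulate([a, a.inverse()]).matrix, np.eye(4), atol=1e-10)

    def test_matches_triple_product(self, rng):
        ts = [compose_affine(random_params(rng)) for _ in range(3)]
        brute = ts[0].matrix @ ts[1].matrix @ ts[2].matrix
        np.testing.assert_allclose(accumulate(ts).matrix, brute, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])

    def test_single_warp_equals_sequential_warps(self, smooth_volume):
        rng = np.random.default_rng(7)
        a1 = compose_affine(GeometricParams(t=(0.05, 0, 0), r=(0.1, 0, 0),
                                            s=np.ones(3), h=np.zeros(3)))
        a2 = compose_affine(GeometricParams(t=(0, -0.04, 0), r=(0, 0.08, 0),
                                            s=np.ones(3), h=np.zeros(3)))
        sequential = warp_volume(warp_volume(smooth_volume, a1), a2)
        single = warp_volume(smooth_volume, accumulate([a1, a2]))
        interior = (slice(4, -4),) * 3
        cc = np.corrcoef(sequential[interior].ravel(), single[interior].ravel())[0, 1]
        assert cc > 0.999


class TestSerialization:
    def test_text_round_trip(self, rng, tmp_path):
        a = compose_affine(random_params(rng))
        path = tmp_path / "affine.txt"
        a.save(path)
        b = AffineTransform.load(path)
        np.testing.assert_allclose(a.matrix, b.matrix)
        assert len(path.read_text().strip().splitlines()) == 4

    def test_params_vector_round_trip(self, rng):
        p = random_params(rng)
        np.testing.assert_allclose(
            GeometricParams.from_vector(p.as_vector()).as_vector(), p.as_vector())
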