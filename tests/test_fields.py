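import numpy as np
import pytest

from morphhead import (
    ImageVolume,
    RigidTransform,
    VectorField,
    compose_fields,
    invert_field,
    jacobian_determinant,
    load_field,
    load_image,
    sample_trilinear,
    save_field,
    save_image,
    warp_image,
)
from morphhead.fields import ConventionError, DomainError

from conftest import affine_field, constant_field


class TestSampling:
    def test_constant_field_reproduced_anywhere(self):
        f = constant_field((8, 8, 8), 2.0, (1.0, 2.0, 3.0))
        pts = np.array([[3.1, 7.7, 9.2], [0.0, 0.0, 0.0], [14.0, 14.0, 14.0]])
        assert np.allclose(sample_trilinear(f, pts), [1.0, 2.0, 3.0])

    def test_linear_field_exact(self):
        # trilinear interpolation reproduces affine functions of position
        A = 0.1 * np.eye(3)
        f = affine_field((9, 9, 9), 1.5, A, np.zeros(3))
        rng = np.random.default_rng(0)
        pts = rng.uniform(1.0, 11.0, size=(50, 3))
        assert np.allclose(sample_trilinear(f, pts), 0.1 * pts, atol=1e-12)

    def test_voxel_center_returns_stored_value(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(5, 6, 7))
        img = ImageVolume(data, np.diag([2.0, 2.0, 2.0, 1.0]))
        assert sample_trilinear(img, [[4.0, 6.0, 8.0]])[0] == pytest.approx(
            data[2, 3, 4], abs=1e-14
        )

    def test_outside_domain_raises_and_names_point(self):
        f = constant_field((4, 4, 4), 1.0, (0.0, 0.0, 0.0))
        with pytest.raises(DomainError, match="10"):
            sample_trilinear(f, [[10.0, 0.0, 0.0]])

    def test_clamp_within_half_voxel(self):
        f = constant_field((4, 4, 4), 1.0, (5.0, 0.0, 0.0))
        out = sample_trilinear(f, [[-0.4, 1.0, 1.0]])
        assert out[0, 0] == 5.0


class TestWarpImage:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(2)
        img = ImageVolume(rng.normal(size=(6, 6, 6)), np.eye(4))
        u = constant_field((6, 6, 6), 1.0, (0.0, 0.0, 0.0))
        assert np.allclose(warp_image(img, u).data, img.data)

    def test_impulse_moves_opposite_to_resampling_field(self):
        # out(x) = in(x + a): an impulse at voxel p appears at p - a
        data = np.zeros((9, 9, 9))
        data[6, 4, 4] = 1.0
        img = ImageVolume(data, np.eye(4))
        u = constant_field((9, 9, 9), 1.0, (2.0, 0.0, 0.0))
        out = warp_image(img, u)
        assert out.data[4, 4, 4] == pytest.approx(1.0)
        assert out.data[6, 4, 4] == pytest.approx(0.0)

    def test_nearest_preserves_mask_values(self):
        rng = np.random.default_rng(3)
        mask = ImageVolume(
            (rng.random((8, 8, 8)) > 0.5).astype(np.uint8), np.eye(4), is_mask=True
        )
        u = affine_field((8, 8, 8), 1.0, 0.05 * np.eye(3), [0.3, -0.2, 0.1])
        out = warp_image(mask, u, interp="nearest")
        assert set(np.unique(out.data)) <= {0, 1}
        assert out.is_mask

    def test_forward_field_rejected(self):
        img = ImageVolume(np.zeros((4, 4, 4)), np.eye(4))
        u = constant_field((4, 4, 4), 1.0, (0.0, 0.0, 0.0), convention="forward")
        with pytest.raises(ConventionError):
            warp_image(img, u)


class TestCompose:
    def test_zero_second_field(self):
        # shrinking map keeps the image of id+u1 inside the grid
        u1 = affine_field((8, 8, 8), 1.0, -0.04 * np.eye(3), [0.2, 0.1, 0.1])
        u2 = constant_field((8, 8, 8), 1.0, (0, 0, 0))
        total = compose_fields(u1, u2)
        assert np.allclose(total.data, u1.data)

    def test_constants_add(self):
        u1 = constant_field((8, 8, 8), 1.0, (1.0, 0.0, 0.0))
        u2 = constant_field((8, 8, 8), 1.0, (0.0, 2.0, 0.5))
        for mode in ("compose", "sum"):
            total = compose_fields(u1, u2, mode=mode, tol_vox=2.0)
            assert np.allclose(total.data, [1.0, 2.0, 0.5])

    def test_affine_matrix_oracle(self):
        # (id+u2)∘(id+u1) − id computed by matrix algebra
        # id+u1 must keep grid points inside the grid: shrinking + small
        # positive offset (trilinear sampling of u2 is exact only inside)
        A1, b1 = -0.06 * np.eye(3) + 0.005, np.array([0.3, 0.2, 0.1])
        A2, b2 = -0.03 * np.eye(3), np.array([-0.1, 0.3, 0.2])
        shape, sp = (10, 10, 10), 1.0
        u1 = affine_field(shape, sp, A1, b1)
        u2 = affine_field(shape, sp, A2, b2)
        total = compose_fields(u1, u2)
        # x' = (I+A2)((I+A1)x + b1) + b2 - x
        M = (np.eye(3) + A2) @ (np.eye(3) + A1) - np.eye(3)
        c = (np.eye(3) + A2) @ b1 + b2
        expected = affine_field(shape, sp, M, c)
        assert np.allclose(total.data, expected.data, atol=1e-10)

    def test_associativity_on_affine_fields(self):
        shape, sp = (8, 8, 8), 1.0
        fields = [
            affine_field(shape, sp, -0.02 * np.eye(3), [0.1, 0.05, 0.05]),
            affine_field(shape, sp, -0.03 * np.eye(3), [0.05, 0.2, 0.05]),
            affine_field(shape, sp, -0.01 * np.eye(3), [0.05, 0.05, 0.1]),
        ]
        left = compose_fields(compose_fields(fields[0], fields[1]), fields[2])
        right = compose_fields(fields[0], compose_fields(fields[1], fields[2]))
        assert np.allclose(left.data, right.data, atol=1e-9)

    def test_convention_mismatch_rejected(self):
        u1 = constant_field((4, 4, 4), 1.0, (1, 0, 0), convention="resampling")
        u2 = constant_field((4, 4, 4), 1.0, (1, 0, 0), convention="forward")
        with pytest.raises(ConventionError):
            compose_fields(u1, u2)


class TestInvert:
    def test_constant_field(self):
        u = constant_field((8, 8, 8), 1.0, (0.8, -0.3, 0.2))
        v = invert_field(u)
        assert np.allclose(v.data, [-0.8, 0.3, -0.2], atol=1e-3)
        assert v.convention == "forward"

    def test_affine_closed_form(self):
        A, b = 0.1 * np.eye(3), np.array([0.5, -0.3, 0.2])
        u = affine_field((12, 12, 12), 1.0, A, b)
        v = invert_field(u, tol=1e-6, max_iter=200)
        # (id+u)^{-1}: x -> (I+A)^{-1}(x - b), so v(x) = (Minv - I)x - Minv b
        Minv = np.linalg.inv(np.eye(3) + A)
        expected = affine_field((12, 12, 12), 1.0, Minv - np.eye(3), -Minv @ b)
        # boundary voxels whose preimage leaves the grid are clamped during
        # the fixed-point iteration; the closed form holds on the interior
        core = (slice(2, -2),) * 3
        assert np.allclose(v.data[core], expected.data[core], atol=1e-5)

    def test_inverse_consistency(self):
        A, b = np.diag([0.08, -0.05, 0.06]), np.array([0.3, 0.2, -0.1])
        u = affine_field((12, 12, 12), 1.0, A, b)
        v = invert_field(u, tol=1e-8, max_iter=300)
        v.convention = u.convention  # compose requires matching tags
        total = compose_fields(u, v, tol_vox=3.0)
        core = (slice(2, -2),) * 3  # boundary voxels clamp, see above
        assert np.abs(total.data[core]).max() <= 2e-8


class TestRigidTransform:
    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(4)
        q = rng.normal(size=3)
        th = np.linalg.norm(q)
        k = q / th
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
        t = RigidTransform(R, rng.normal(size=3))
        comp = t.compose(t.inverse())
        assert np.allclose(comp.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(comp.translation, 0.0, atol=1e-10)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestJacobianAndIO:
    def test_jacobian_of_affine_field(self):
        A = np.diag([0.2, -0.1, 0.05])
        u = affine_field((10, 10, 10), 1.0, A, np.zeros(3))
        det = jacobian_determinant(u)
        expected = np.linalg.det(np.eye(3) + A)
        interior = det[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, expected, atol=1e-10)

    def test_nifti_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        img = ImageVolume(rng.normal(size=(5, 6, 7)), np.diag([2, 2, 2, 1.0]))
        save_image(img, tmp_path / "img.nii.gz")
        back = load_image(tmp_path / "img.nii.gz")
        assert np.allclose(back.data, img.data, atol=1e-6)
        assert np.allclose(back.affine, img.affine)

        u = affine_field((5, 6, 7), 2.0, 0.03 * np.eye(3), [1, 2, 3])
        save_field(u, tmp_path / "field.nii.gz")
        back_u = load_field(tmp_path / "field.nii.gz")
        assert back_u.convention == "resampling"
        assert np.allclose(back_u.data, u.data, atol=1e-6)

    def test_mask_invariant_enforced(self):
        with pytest.raises(ValueError):
            ImageVolume(np.full((3, 3, 3), 2.0), np.eye(4), is_mask=True)
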