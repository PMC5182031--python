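"""Warp algebra: Jacobians, fixel reorientation, FC and FDC."""

import numpy as np
import pytest

from fixel.core import FixelGrid
from fixel.morphometry import (DeformationField, DisplacementField,
                               FoldedWarpError, DegenerateWarpError,
                               deformation_to_displacement,
                               displacement_to_deformation, fc_fixel_map,
                               fc_gram_schmidt_oracle, fibre_cross_section,
                               jacobian, modulate_fdc, reorient_fixel)

SHEAR3 = np.array([[1.0, 0, 0], [0.5, 1.0, 0], [0, 0, 1.0]])


def affine_deformation(A, t, shape, affine=np.eye(4)):
    from fixel.morphometry import _grid_positions
    pos = _grid_positions(shape, affine)
    return DeformationField(shape, affine, pos @ np.asarray(A).T + t)


class TestFields:
    def test_zero_displacement_is_identity_deformation(self):
        d = DisplacementField((4, 3, 2), np.eye(4), np.zeros((4, 3, 2, 3)))
        f = displacement_to_deformation(d)
        np.testing.assert_allclose(
            f.positions, DeformationField.identity((4, 3, 2),
                                                   np.eye(4)).positions)

    def test_constant_displacement_shifts(self):
        t = np.array([1.0, -2.0, 0.5])
        d = DisplacementField((3, 3, 1), np.eye(4),
                              np.broadcast_to(t, (3, 3, 1, 3)).copy())
        f = displacement_to_deformation(d)
        ident = DeformationField.identity((3, 3, 1), np.eye(4))
        np.testing.assert_allclose(f.positions - ident.positions,
                                   np.broadcast_to(t, (3, 3, 1, 3)))

    def test_round_trip(self, rng):
        d = DisplacementField((4, 4, 1), np.eye(4),
                              rng.normal(size=(4, 4, 1, 3)))
        back = deformation_to_displacement(displacement_to_deformation(d))
        np.testing.assert_allclose(back.displacements, d.displacements,
                                   atol=1e-12)

    def test_nonfinite_rejected(self):
        v = np.zeros((2, 2, 1, 3))
        v[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            DeformationField((2, 2, 1), np.eye(4), v)


class TestJacobian:
    def test_identity_deformation(self):
        f = DeformationField.identity((4, 4, 2), np.eye(4))
        J = jacobian(f)
        np.testing.assert_allclose(J.J, np.broadcast_to(np.eye(3),
                                                        (4, 4, 2, 3, 3)),
                                   atol=1e-12)
        np.testing.assert_allclose(J.det, 1.0)

    def test_affine_map_exact_including_boundary(self, rng):
        A = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        t = rng.normal(size=3)
        f = affine_deformation(A, t, (5, 4, 3))
        J = jacobian(f)
        np.testing.assert_allclose(J.J, np.broadcast_to(A, (5, 4, 3, 3, 3)),
                                   atol=1e-9)

    def test_anisotropic_voxels_handled_via_affine(self):
        aff = np.diag([2.0, 0.5, 1.0, 1.0])
        A = np.diag([2.0, 1.0, 1.0])
        f = affine_deformation(A, np.zeros(3), (4, 4, 1), aff)
        J = jacobian(f)
        np.testing.assert_allclose(J.det, 2.0, atol=1e-12)

    def test_singleton_axis_contributes_identity(self):
        f = DeformationField.identity((4, 4, 1), np.eye(4))
        J = jacobian(f)
        np.testing.assert_allclose(
            J.J[..., :, 2],
            np.broadcast_to([0.0, 0.0, 1.0], (4, 4, 1, 3)), atol=1e-12)


class TestReorient:
    def test_identity_and_rotation(self, rng):
        v = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(reorient_fixel(v, np.eye(3)), v)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        np.testing.assert_allclose(reorient_fixel(v, R), R @ v, atol=1e-12)

    def test_shear_hand_computed(self):
        out = reorient_fixel([1.0, 0, 0], SHEAR3)
        np.testing.assert_allclose(out, np.array([1.0, 0.5, 0]) / np.sqrt(1.25),
                                   atol=1e-12)
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_degenerate(self):
        with pytest.raises(DegenerateWarpError):
            reorient_fixel([1.0, 0, 0], np.diag([0.0, 1.0, 1.0]))


class TestFibreCrossSection:
    def test_identity(self):
        assert fibre_cross_section([1.0, 0, 0], np.eye(3)) == pytest.approx(1.0)

    def test_scale_invariance(self):
        # pure length scaling of a bundle along x leaves FC at 1
        T = np.diag([2.0, 1.0, 1.0])
        assert fibre_cross_section([1.0, 0, 0], T) == pytest.approx(1.0)

    def test_shear_with_reorientation_convention(self):
        # template direction = image of the bundle axis under the inverse map
        v_t = reorient_fixel([1.0, 0, 0], np.linalg.inv(SHEAR3))
        fc = fibre_cross_section(v_t, SHEAR3)
        assert fc == pytest.approx(np.sqrt(1.25), abs=1e-12)
        assert fc > 1.0

    def test_folded_and_degenerate_errors(self):
        with pytest.raises(FoldedWarpError):
            fibre_cross_section([1.0, 0, 0], np.diag([-1.0, 1.0, 1.0]))

    def test_identity_fc_times_norm_is_det(self, rng):
        for _ in range(50):
            J = np.eye(3) + 0.4 * rng.normal(size=(3, 3))
            if np.linalg.det(J) <= 0.1:
                continue
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            fc = fibre_cross_section(v, J)
            assert fc * np.linalg.norm(J @ v) == pytest.approx(
                np.linalg.det(J), rel=1e-12)

    def test_rotation_gives_unity_and_frame_equivariance(self, rng):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zxy", [40, -25, 10], degrees=True).as_matrix()
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        assert fibre_cross_section(v, R) == pytest.approx(1.0)
        J = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
        assert np.linalg.det(J) > 0
        assert fibre_cross_section(R @ v, R @ J @ R.T) == pytest.approx(
            fibre_cross_section(v, J), rel=1e-12)


class TestGramSchmidtOracle:
    def test_identity(self):
        assert fc_gram_schmidt_oracle([0, 0, 1.0], np.eye(3)) == pytest.approx(1.0)

    def test_diagonal_perpendicular_area(self):
        J = np.diag([1.7, 0.8, 1.3])
        assert fc_gram_schmidt_oracle([1.0, 0, 0], J) == pytest.approx(
            0.8 * 1.3, rel=1e-12)

    def test_equivalence_on_random_jacobians(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 1000:
            J = np.eye(3) + 0.5 * rng.normal(size=(3, 3))
            if np.linalg.det(J) < 0.2:
                continue
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            assert abs(fibre_cross_section(v, J)
                       - fc_gram_schmidt_oracle(v, J)) < 1e-9
            checked += 1


class TestModulateFDC:
    def test_arithmetic(self):
        np.testing.assert_allclose(modulate_fdc([1.0, 0.0, 0.8],
                                                [1.0, 2.0, 1.25]),
                                   [1.0, 0.0, 1.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            modulate_fdc([1.0, 2.0], [1.0])


class TestFCFixelMap:
    def test_identity_warp_gives_unit_fc(self, small_grid):
        warp = DeformationField.identity(small_grid.shape, small_grid.affine)
        out = fc_fixel_map(small_grid, warp)
        np.testing.assert_allclose(out.values["fc"], 1.0, atol=1e-12)
        np.testing.assert_array_equal(out.directions, small_grid.directions)

    def test_folded_warp_reports_voxels(self, small_grid):
        warp = affine_deformation(np.diag([-1.0, 1.0, 1.0]), np.zeros(3),
                                  small_grid.shape)
        with pytest.raises(FoldedWarpError, match=r"\(0, 0, 0\)"):
            fc_fixel_map(small_grid, warp)

    def test_log_option(self, small_grid):
        warp = affine_deformation(np.diag([1.0, 2.0, 1.0]), np.zeros(3),
                                  small_grid.shape)
        out = fc_fixel_map(small_grid, warp, log_transform=True)
        lin = fc_fixel_map(small_grid, warp)
        np.testing.assert_allclose(out.values["fc"],
                                   np.log(lin.values["fc"]), atol=1e-12)
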