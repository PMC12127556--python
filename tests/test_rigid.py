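import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from breqa import (
    CorrespondenceSet,
    Geometry,
    LabelMap,
    RigidTransform,
    VectorField,
    bone_bre,
    compute_bre,
    extract_correspondences,
    fit_rigid,
    split_connected_components,
)
from breqa.rigid import (
    InvalidPointsError,
    LabelNotFoundError,
    OutOfFieldError,
    UnderdeterminedError,
)

from _oracles import axis_angle_grid, flood_fill_components, rigid_objective
from conftest import random_rigid


def corr_from_points(X, Y):
    return CorrespondenceSet(X=X, Y=Y)


class TestFitRigid:
    def test_identity_when_points_coincide(self, rng):
        X = rng.normal(size=(4, 3)) * 10
        tf = fit_rigid(corr_from_points(X, X.copy()))
        np.testing.assert_allclose(tf.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.t, 0, atol=1e-12)

    def test_pure_translation_recovered(self, unit_cube_corners):
        Y = unit_cube_corners + np.array([5.0, 0.0, 0.0])
        tf = fit_rigid(corr_from_points(unit_cube_corners, Y))
        np.testing.assert_allclose(tf.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.t, [5.0, 0.0, 0.0], atol=1e-12)

    def test_exact_rigid_recovery_90_degrees(self, unit_cube_corners):
        R90 = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        Y = unit_cube_corners @ R90.T + t
        tf = fit_rigid(corr_from_points(unit_cube_corners, Y))
        np.testing.assert_allclose(tf.R, R90, atol=1e-12)
        np.testing.assert_allclose(tf.t, t, atol=1e-12)
        assert compute_bre(corr_from_points(unit_cube_corners, Y), tf) < 1e-12

    def test_noisy_fit_beats_dense_rotation_grid(self, rng):
        X = rng.normal(size=(50, 3)) * 20
        R, t = random_rigid(rng, max_angle=0.8)
        Y = X @ R.T + t + rng.normal(0, 0.5, (50, 3))
        tf = fit_rigid(corr_from_points(X, Y))
        ours = rigid_objective(X, Y, tf.R)
        grid = axis_angle_grid(step_deg=5.0, n_axes=400)
        best_grid = min(rigid_objective(X, Y, Rg) for Rg in grid)
        assert ours <= best_grid + 1e-9

    def test_agrees_with_independent_scipy_solver(self, rng):
        X = rng.normal(size=(30, 3)) * 15
        R, t = random_rigid(rng)
        Y = X @ R.T + t + rng.normal(0, 0.2, (30, 3))
        tf = fit_rigid(corr_from_points(X, Y))
        xc = X - X.mean(axis=0)
        yc = Y - Y.mean(axis=0)
        R_check = Rotation.align_vectors(yc, xc)[0].as_matrix()
        np.testing.assert_allclose(tf.R, R_check, atol=1e-8)

    def test_underdetermined_and_invalid_inputs_raise(self):
        with pytest.raises(UnderdeterminedError):
            fit_rigid(corr_from_points(np.zeros((2, 3)), np.zeros((2, 3))))
        X = np.random.default_rng(0).normal(size=(5, 3))
        Y = X.copy()
        Y[0, 0] = np.nan
        with pytest.raises(InvalidPointsError):
            fit_rigid(corr_from_points(X, Y))

    def test_no_reflection_on_near_planar_sets(self, rng):
        """A mirrored near-planar cloud must still yield det(R) = +1."""
        for _ in range(200):
            X = rng.normal(size=(20, 3))
            X[:, 2] *= 1e-8  # nearly coplanar
            Y = X @ np.diag([1.0, 1.0, -1.0]) + rng.normal(0, 1e-6, (20, 3))
            tf = fit_rigid(corr_from_points(X, Y))
            assert abs(np.linalg.det(tf.R) - 1.0) < 1e-9

    def test_collinear_points_still_return_a_proper_minimizer(self):
        X = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        Y = X + 2.0
        tf = fit_rigid(corr_from_points(X, Y))
        assert abs(np.linalg.det(tf.R) - 1.0) < 1e-9


class TestComputeBre:
    def test_global_rigid_field_scores_zero(self, rng):
        X = rng.normal(size=(40, 3)) * 30
        R, t = random_rigid(rng)
        Y = X @ R.T + t
        corr = corr_from_points(X, Y)
        assert compute_bre(corr, fit_rigid(corr)) < 1e-9

    def test_zero_displacement_scores_zero(self, rng):
        X = rng.normal(size=(25, 3))
        corr = corr_from_points(X, X.copy())
        assert compute_bre(corr, fit_rigid(corr)) == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_scaling_of_cube_corners_closed_form(self, unit_cube_corners):
        c = unit_cube_corners.mean(axis=0)
        Y = c + 1.1 * (unit_cube_corners - c)
        corr = corr_from_points(unit_cube_corners, Y)
        bre = compute_bre(corr, fit_rigid(corr))
        # mean distance of a unit-cube corner to the centre is sqrt(0.75)
        assert bre == pytest.approx(0.1 * np.sqrt(0.75), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CorrespondenceSet(X=np.zeros((4, 3)), Y=np.zeros((5, 3)))


class TestRigidProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bre_invariant_under_rigid_composition(self, seed):
        """Composing any rigid (Q, s) after the deformation leaves BRE unchanged."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 3)) * 10
        Y = X + rng.normal(0, 1.0, (15, 3))
        Q, s = random_rigid(rng, max_angle=2.5, max_shift=20.0)
        corr1 = corr_from_points(X, Y)
        corr2 = corr_from_points(X, Y @ Q.T + s)
        bre1 = compute_bre(corr1, fit_rigid(corr1))
        bre2 = compute_bre(corr2, fit_rigid(corr2))
        assert bre2 == pytest.approx(bre1, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.8, 1.2))
    def test_scaling_closed_form_on_random_point_sets(self, seed, s):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 3)) * 8
        c = X.mean(axis=0)
        Y = c + s * (X - c)
        corr = corr_from_points(X, Y)
        bre = compute_bre(corr, fit_rigid(corr))
        expected = abs(s - 1.0) * np.mean(np.linalg.norm(X - c, axis=1))
        assert bre == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bre_nonnegative_and_zero_only_for_rigid(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3)) * 10
        Y = X + rng.normal(0, 1.0, (20, 3))
        corr = corr_from_points(X, Y)
        assert compute_bre(corr, fit_rigid(corr)) >= 0.0


class TestExtractCorrespondences:
    def make_coincident_case(self, rng):
        geom = Geometry(origin=(1.0, 2.0, 3.0), spacing=(2.0, 1.0, 1.5))
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[2:4, 3:5, 4:6] = 1  # 8-voxel bone... pad to 10 below
        labels[5, 5, 5] = 1
        labels[5, 5, 6] = 1
        dvf_data = rng.normal(size=(8, 8, 8, 3))
        return LabelMap(labels, geom), VectorField(dvf_data, geom)

    def test_exact_lookup_on_coincident_grids(self, rng):
        labels, dvf = self.make_coincident_case(rng)
        corr = extract_correspondences(dvf, labels, 1)
        idx = labels.voxel_indices(1)
        np.testing.assert_allclose(corr.X, labels.geometry.world_from_index(idx), atol=1e-12)
        stored = dvf.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        np.testing.assert_allclose(corr.Y - corr.X, stored, atol=1e-12)

    def test_half_voxel_offset_grid_averages_neighbours(self, rng):
        geom = Geometry(origin=(0.0, 0.0, 0.0), spacing=(2.0, 2.0, 2.0))
        dvf = VectorField(rng.normal(size=(6, 6, 6, 3)), geom)
        # label grid shifted half a voxel along x: centres midway between DVF voxels
        lgeom = Geometry(origin=(1.0, 0.0, 0.0), spacing=(2.0, 2.0, 2.0))
        labels = np.zeros((5, 6, 6), dtype=np.int32)
        labels[2, 3, 3] = 1
        corr = extract_correspondences(dvf, LabelMap(labels, lgeom), 1)
        expected = 0.5 * (dvf.data[2, 3, 3] + dvf.data[3, 3, 3])
        np.testing.assert_allclose(corr.Y[0] - corr.X[0], expected, atol=1e-12)

    def test_missing_label_raises(self, rng):
        labels, dvf = self.make_coincident_case(rng)
        with pytest.raises(LabelNotFoundError):
            extract_correspondences(dvf, labels, 99)

    def test_bone_mostly_outside_field_raises_with_fraction(self, rng):
        geom = Geometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0))
        labels = np.zeros((10, 4, 4), dtype=np.int32)
        labels[:, 1, 1] = 1  # spans x = 0..9
        small = Geometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0))
        dvf = VectorField(np.zeros((5, 4, 4, 3)), small)  # covers x = 0..4 only
        with pytest.raises(OutOfFieldError) as err:
            extract_correspondences(dvf, LabelMap(labels, geom), 1)
        assert err.value.fraction == pytest.approx(0.5)

    def test_stride_subsamples_voxels(self, rng):
        labels, dvf = self.make_coincident_case(rng)
        full = extract_correspondences(dvf, labels, 1)
        strided = extract_correspondences(dvf, labels, 1, stride=2)
        assert strided.n == int(np.ceil(full.n / 2))


class TestBoneBre:
    def test_rigid_bone_scores_zero_end_to_end(self):
        from conftest import rigid_bone_case

        labels, dvf, _ = rigid_bone_case(seed=3)
        for label in (1, 2, 3):
            result = bone_bre(dvf, labels, label)
            assert result.bre < 1e-9

    def test_constructed_residual_matches_amplitude_and_oracle(self):
        """Residuals orthogonal to the rigid modes leave identity optimal."""
        from breqa.synthetic import _constructed_residual

        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 3)) * 12
        c = X.mean(axis=0)
        e = _constructed_residual(X - c, rng)
        alpha = 0.4
        Y = X + alpha * e
        corr = corr_from_points(X, Y)
        tf = fit_rigid(corr)
        bre = compute_bre(corr, tf)
        expected = alpha * np.mean(np.linalg.norm(e, axis=1))
        # identity is optimal to first order in alpha, so expected is met to O(alpha^2)
        assert bre == pytest.approx(expected, rel=1e-2)
        assert bre <= expected
        # brute-force grid confirms no rotation beats the identity
        grid = axis_angle_grid(step_deg=10.0, n_axes=150)
        best_grid = min(rigid_objective(X, Y, Rg) for Rg in grid)
        assert rigid_objective(X, Y, tf.R) <= best_grid + 1e-9
        np.testing.assert_allclose(tf.R, np.eye(3), atol=1e-2)

    def test_sheared_bone_scores_strictly_worse_than_rigid_one(self):
        from breqa import Violation
        from conftest import rigid_bone_case

        labels, dvf, _ = rigid_bone_case(
            seed=5, violations={2: Violation(mode="shear", param=0.15)}
        )
        rigid = bone_bre(dvf, labels, 1)
        sheared = bone_bre(dvf, labels, 2)
        assert sheared.bre > rigid.bre + 0.1

    def test_tiny_bone_flagged_too_small(self, rng):
        geom = Geometry((0, 0, 0), (1, 1, 1))
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[2:4, 2, 2] = 1  # 2 voxels < default minimum of 10
        dvf = VectorField(np.zeros((6, 6, 6, 3)), geom)
        result = bone_bre(dvf, LabelMap(labels, geom), 1)
        assert result.flag == "too-small"
        assert result.bre is None and result.transform is None


class TestSplitConnectedComponents:
    def geom(self):
        return Geometry((0, 0, 0), (1, 1, 1))

    def test_two_disjoint_blobs_get_two_labels(self):
        arr = np.zeros((10, 10, 10), dtype=np.int32)
        arr[1:3, 1:3, 1:3] = 5
        arr[7:9, 7:9, 7:9] = 5
        out, mapping = split_connected_components(LabelMap(arr, self.geom()))
        assert mapping == {5: [1, 2]}
        assert out.present_labels() == [1, 2]

    def test_single_blob_is_unchanged_up_to_relabel(self):
        arr = np.zeros((6, 6, 6), dtype=np.int32)
        arr[2:5, 2:5, 2:5] = 9
        out, mapping = split_connected_components(LabelMap(arr, self.geom()))
        assert mapping == {9: [1]}
        np.testing.assert_array_equal(out.labels > 0, arr > 0)

    def test_diagonal_touch_counts_as_connected(self):
        """26-connectivity keeps voxels sharing only a corner in one piece."""
        arr = np.zeros((4, 4, 4), dtype=np.int32)
        arr[0, 0, 0] = 1
        arr[1, 1, 1] = 1
        _, mapping = split_connected_components(LabelMap(arr, self.geom()))
        assert len(mapping[1]) == 1

    def test_random_islands_match_flood_fill_oracle(self, rng):
        arr = np.zeros((16, 16, 16), dtype=np.int32)
        mask = rng.random((16, 16, 16)) < 0.04
        arr[mask] = 2
        out, mapping = split_connected_components(LabelMap(arr, self.geom()))
        assert len(mapping[2]) == flood_fill_components(mask)
        # output labels partition the original mask
        np.testing.assert_array_equal(out.labels > 0, mask)


def test_rigid_transform_rejects_reflections_and_non_orthogonal():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 1.001, np.zeros(3))
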