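"""Rigid-transform estimation, application and composition."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicealign.core_geometry import (
    DegenerateGeometryError,
    DimensionalityError,
    InsufficientCorrespondenceError,
    RigidTransform,
    Slice,
    apply_transform,
    compose,
    estimate_rigid_transform,
    rotation_angle,
)


class TestApplyTransform:
    def test_identity_leaves_coords_unchanged(self, rng):
        coords = rng.normal(size=(10, 2))
        out = apply_transform(RigidTransform.identity(2), coords)
        np.testing.assert_array_equal(out, coords)

    def test_quarter_turn_moves_unit_x_to_unit_y(self):
        t = RigidTransform.from_angle(90.0)
        np.testing.assert_allclose(
            apply_transform(t, np.array([[1.0, 0.0]])), [[0.0, 1.0]], atol=1e-12
        )

    @pytest.mark.parametrize("dim", [2, 3])
    def test_matches_per_point_matrix_vector_oracle(self, rng, dim):
        if dim == 2:
            t = RigidTransform.from_angle(rng.uniform(0, 360), rng.normal(size=2))
        else:
            t = RigidTransform.from_axis_angle(rng.normal(size=3), rng.uniform(0, 180),
                                               rng.normal(size=3))
        coords = rng.normal(size=(50, dim))
        expected = np.array([t.rotation @ x + t.translation for x in coords])
        np.testing.assert_allclose(apply_transform(t, coords), expected, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DimensionalityError):
            apply_transform(RigidTransform.identity(2), np.zeros((4, 3)))

    def test_input_not_mutated(self, rng):
        coords = rng.normal(size=(5, 2))
        before = coords.copy()
        apply_transform(RigidTransform.from_angle(33.0, (1, 2)), coords)
        np.testing.assert_array_equal(coords, before)


class TestCompose:
    def test_identity_is_neutral(self):
        t = RigidTransform.from_angle(47.0, (1.0, -2.0))
        out = compose(RigidTransform.identity(2), t)
        np.testing.assert_allclose(out.rotation, t.rotation, atol=1e-12)
        np.testing.assert_allclose(out.translation, t.translation, atol=1e-12)

    def test_rotation_angles_add(self):
        out = compose(RigidTransform.from_angle(30.0), RigidTransform.from_angle(60.0))
        assert rotation_angle(out) == pytest.approx(90.0, abs=1e-10)
        np.testing.assert_allclose(out.translation, [0.0, 0.0], atol=1e-12)

    def test_equals_sequential_application(self, rng):
        a = RigidTransform.from_angle(rng.uniform(0, 360), rng.normal(size=2))
        b = RigidTransform.from_angle(rng.uniform(0, 360), rng.normal(size=2))
        coords = rng.normal(size=(30, 2))
        np.testing.assert_allclose(
            apply_transform(compose(a, b), coords),
            apply_transform(b, apply_transform(a, coords)),
            atol=1e-10,
        )

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DimensionalityError):
            compose(RigidTransform.identity(2), RigidTransform.identity(3))


class TestEstimateRigidTransform:
    def test_self_alignment_gives_identity(self, rng):
        coords = rng.normal(size=(12, 2))
        t = estimate_rigid_transform(coords, coords, [(i, i) for i in range(12)])
        np.testing.assert_allclose(t.rotation, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(t.translation, np.zeros(2), atol=1e-10)

    def test_recovers_constructed_motion(self, rng):
        truth = RigidTransform.from_angle(135.0, (3.0, -2.0))
        src = rng.normal(size=(25, 2))
        dst = apply_transform(truth, src)
        t = estimate_rigid_transform(src, dst, [(i, i) for i in range(25)])
        assert rotation_angle(t) == pytest.approx(135.0, abs=1e-9)
        np.testing.assert_allclose(t.translation, [3.0, -2.0], atol=1e-9)

    def test_mirrored_target_still_yields_proper_rotation(self, rng):
        """A reflected target makes det(V·Uᵀ) = −1; the result must stay a
        proper rotation and match the best angle found by 0.01°-grid search."""
        src = rng.normal(size=(15, 2))
        dst = src @ np.diag([1.0, -1.0])  # pure reflection
        t = estimate_rigid_transform(src, dst, [(i, i) for i in range(15)])
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-10)

        def residual(theta_deg):
            c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
            rot = np.array([[c, -s], [s, c]])
            moved = (src - src.mean(0)) @ rot.T
            return ((moved - (dst - dst.mean(0))) ** 2).sum()

        grid = np.arange(0.0, 360.0, 0.01)
        best = min(residual(g) for g in grid)
        got = residual(rotation_angle(t))
        assert got <= best + 1e-6

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientCorrespondenceError):
            estimate_rigid_transform(np.zeros((3, 2)), np.zeros((3, 2)), [(0, 0)])

    def test_collinear_pairs_raise_degenerate_error(self):
        src = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(src, src * 2.0 + 1.0, [(i, i) for i in range(5)])

    def test_invariant_to_common_pair_permutation(self, rng):
        truth = RigidTransform.from_angle(77.0, (0.5, 0.5))
        src = rng.normal(size=(20, 2))
        dst = apply_transform(truth, src)
        pairs = [(i, i) for i in range(20)]
        perm = rng.permutation(20)
        t1 = estimate_rigid_transform(src, dst, pairs)
        t2 = estimate_rigid_transform(src, dst, [pairs[i] for i in perm])
        np.testing.assert_allclose(t1.rotation, t2.rotation, atol=1e-12)
        np.testing.assert_allclose(t1.translation, t2.translation, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.0, 360.0, allow_nan=False), st.integers(0, 2**31 - 1))
    def test_round_trip_recovery_property(self, angle, seed):
        """Known rigid motion with exact correspondences is recovered to 1e-8."""
        local = np.random.default_rng(seed)
        truth = RigidTransform.from_angle(angle, local.normal(size=2) * 10)
        src = local.normal(size=(10, 2))
        dst = apply_transform(truth, src)
        t = estimate_rigid_transform(src, dst, [(i, i) for i in range(10)])
        assert np.linalg.norm(t.rotation - truth.rotation) < 1e-8
        assert np.linalg.norm(t.translation - truth.translation) < 1e-8


class TestRotationAngle:
    def test_identity_is_zero(self):
        assert rotation_angle(RigidTransform.identity(2)) == 0.0

    def test_three_quarter_turn(self):
        assert rotation_angle(RigidTransform.from_angle(270.0)) == pytest.approx(270.0, abs=1e-10)

    def test_round_trip_random_angles(self, rng):
        for theta in rng.uniform(0, 360, size=20):
            got = rotation_angle(RigidTransform.from_angle(theta))
            assert got == pytest.approx(theta % 360.0, abs=1e-9)

    def test_3d_axis_angle_magnitude(self):
        t = RigidTransform.from_axis_angle([0, 0, 1], 30.0)
        assert rotation_angle(t) == pytest.approx(30.0, abs=1e-9)


class TestSerialization:
    def test_json_round_trip_bit_exact(self, rng):
        t = RigidTransform.from_angle(rng.uniform(0, 360), rng.normal(size=2))
        back = RigidTransform.from_json(t.to_json())
        np.testing.assert_array_equal(back.rotation, t.rotation)
        np.testing.assert_array_equal(back.translation, t.translation)

    def test_json_document_fields(self):
        doc = json.loads(RigidTransform.identity(3).to_json())
        assert doc["dim"] == 3
        assert len(doc["rotation"]) == 9
        assert len(doc["translation"]) == 3


class TestSliceInvariants:
    def test_rejects_nonfinite_coords(self):
        with pytest.raises(ValueError, match="non-finite"):
            Slice(coords=[[0.0, np.nan]], features=[[1.0]], feature_names=["g"])

    def test_rejects_duplicate_feature_names(self):
        with pytest.raises(ValueError, match="duplicates"):
            Slice(coords=[[0.0, 0.0]], features=[[1.0, 2.0]], feature_names=["g", "g"])

    def test_rejects_row_mismatch(self):
        with pytest.raises(ValueError, match="row"):
            Slice(coords=[[0.0, 0.0]], features=[[1.0], [2.0]], feature_names=["g"])
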