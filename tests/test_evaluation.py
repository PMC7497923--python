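"""Dice, surface distance, and TRE oracles."""

import numpy as np
import pytest

from mindcycle.deformation import DeformationField
from mindcycle.evaluation import (LandmarkSet, aggregate_reports,
                                  average_surface_distance, dice,
                                  evaluate_case, target_registration_error)
from mindcycle.phantom import PhantomConfig, generate_case
from mindcycle.volume_io import ROIMask


def cube_mask(shape, lo, hi, label=1, spacing=(1.0, 1.0, 1.0)):
    labels = np.zeros(shape, dtype=np.int32)
    labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = label
    return ROIMask(labels, spacing=spacing)


class TestDice:
    def test_identical_masks(self):
        m = cube_mask((8, 8, 4), (2, 2, 1), (5, 5, 3))
        assert dice(m, m, 1) == 1.0

    def test_disjoint_masks(self):
        a = cube_mask((8, 8, 4), (0, 0, 0), (2, 2, 2))
        b = cube_mask((8, 8, 4), (4, 4, 0), (6, 6, 2))
        assert dice(a, b, 1) == 0.0

    def test_half_overlap_cubes(self):
        # 2x2x2 cubes shifted so exactly 4 voxels overlap: 2*4/(8+8) = 0.5
        a = cube_mask((8, 8, 4), (2, 2, 0), (4, 4, 2))
        b = cube_mask((8, 8, 4), (2, 3, 0), (4, 5, 2))
        assert dice(a, b, 1) == 0.5

    def test_both_empty_is_one(self, caplog):
        a = cube_mask((4, 4, 2), (0, 0, 0), (0, 0, 0))
        assert dice(a, a, 1) == 1.0

    def test_symmetry_and_joint_permutation_invariance(self, rng):
        la = rng.integers(0, 2, size=(6, 6, 3)).astype(np.int32)
        lb = rng.integers(0, 2, size=(6, 6, 3)).astype(np.int32)
        a, b = ROIMask(la), ROIMask(lb)
        assert dice(a, b, 1) == dice(b, a, 1)
        perm = rng.permutation(la.size)
        ap = ROIMask(la.reshape(-1)[perm].reshape(la.shape))
        bp = ROIMask(lb.reshape(-1)[perm].reshape(lb.shape))
        assert dice(ap, bp, 1) == pytest.approx(dice(a, b, 1))

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            dice(cube_mask((4, 4, 2), (0, 0, 0), (1, 1, 1)),
                 cube_mask((5, 4, 2), (0, 0, 0), (1, 1, 1)), 1)


class TestASD:
    def test_identical_masks_zero(self):
        m = cube_mask((8, 8, 4), (2, 2, 1), (6, 6, 3))
        assert average_surface_distance(m, m, 1) == 0.0

    def test_single_voxels_three_apart(self):
        a = cube_mask((8, 8, 4), (1, 2, 1), (2, 3, 2))
        b = cube_mask((8, 8, 4), (4, 2, 1), (5, 3, 2))
        assert average_surface_distance(a, b, 1) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        sp = (5.0, 1.0, 1.0)
        a = cube_mask((8, 8, 4), (1, 2, 1), (2, 3, 2), spacing=sp)
        b = cube_mask((8, 8, 4), (4, 2, 1), (5, 3, 2), spacing=sp)
        assert average_surface_distance(a, b, 1) == pytest.approx(15.0)

    def test_exact_and_edt_paths_agree(self, rng):
        la = np.zeros((10, 10, 5), dtype=np.int32)
        lb = np.zeros((10, 10, 5), dtype=np.int32)
        la[2:7, 2:6, 1:4] = 1
        lb[4:9, 3:8, 1:4] = 1
        sp = (1.0, 1.0, 5.0)
        a, b = ROIMask(la, spacing=sp), ROIMask(lb, spacing=sp)
        exact = average_surface_distance(a, b, 1, method="exact")
        edt = average_surface_distance(a, b, 1, method="edt")
        assert abs(exact - edt) < 1e-9

    def test_symmetric(self):
        a = cube_mask((10, 10, 4), (1, 1, 0), (5, 5, 3))
        b = cube_mask((10, 10, 4), (3, 2, 0), (8, 7, 3))
        assert average_surface_distance(a, b, 1) \
            == pytest.approx(average_surface_distance(b, a, 1))

    def test_empty_label_rejected_naming_side(self):
        a = cube_mask((6, 6, 3), (1, 1, 0), (3, 3, 2))
        empty = cube_mask((6, 6, 3), (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError, match="second"):
            average_surface_distance(a, empty, 1)
        with pytest.raises(ValueError, match="first"):
            average_surface_distance(empty, a, 1)


class TestTRE:
    def test_zero_field_coincident_points(self):
        f = DeformationField.zero((8, 8, 4))
        pts = LandmarkSet(np.array([[2.0, 2.0, 1.0], [5.0, 5.0, 2.0]]))
        per_point, mean = target_registration_error(pts, pts, f)
        np.testing.assert_array_equal(per_point, 0.0)
        assert mean == 0.0

    def test_pythagorean_offset(self):
        f = DeformationField.zero((10, 10, 4))
        fixed = LandmarkSet(np.array([[2.0, 2.0, 1.0]]))
        moving = LandmarkSet(np.array([[5.0, 6.0, 1.0]]))
        _, mean = target_registration_error(fixed, moving, f)
        assert mean == pytest.approx(5.0)

    def test_uniform_translation_cancels_offset(self):
        disp = np.zeros((3, 10, 10, 4))
        disp[0], disp[1] = 3.0, 4.0
        f = DeformationField(disp)
        fixed = LandmarkSet(np.array([[2.0, 2.0, 1.0]]))
        moving = LandmarkSet(np.array([[5.0, 6.0, 1.0]]))
        _, mean = target_registration_error(fixed, moving, f)
        assert mean <= 1e-6

    def test_unpaired_sets_rejected(self):
        f = DeformationField.zero((8, 8, 4))
        a = LandmarkSet(np.array([[1.0, 1.0, 1.0]]))
        b = LandmarkSet(np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]))
        with pytest.raises(ValueError):
            target_registration_error(a, b, f)


class TestEvaluateCase:
    @pytest.fixture(scope="class")
    def case(self):
        return generate_case(PhantomConfig(seed=21))

    def test_zero_field_post_equals_pre(self, case):
        f = DeformationField.zero(case.vol_a.data.shape, case.vol_a.spacing)
        r = evaluate_case(case.vol_a, case.vol_b, case.mask_a, case.mask_b,
                          f, case.landmarks_a, case.landmarks_b)
        assert r["dice_post_mean"] == pytest.approx(r["dice_pre_mean"])
        assert r["tre_post_mm"] == pytest.approx(r["tre_pre_mm"])
        assert r["folding_fraction"] == 0.0

    def test_ground_truth_field_recovers_alignment(self, case):
        from mindcycle.deformation import warp_labels
        r = evaluate_case(case.vol_a, case.vol_b, case.mask_a, case.mask_b,
                          case.gt_field, case.landmarks_a, case.landmarks_b)
        # generator-consistency oracle: warp the mask directly
        warped = ROIMask(warp_labels(case.mask_b.labels, case.gt_field),
                         spacing=case.mask_b.spacing)
        want = np.mean([dice(case.mask_a, warped, lab) for lab in (1, 2)])
        assert r["dice_post_mean"] == pytest.approx(want, abs=0.02)
        assert r["dice_post_mean"] > r["dice_pre_mean"]
        assert r["tre_post_mm"] < 1e-9  # landmarks constructed via the field

    def test_requires_masks_or_landmarks(self, case):
        f = DeformationField.zero(case.vol_a.data.shape)
        with pytest.raises(ValueError):
            evaluate_case(case.vol_a, case.vol_b, None, None, f)


def test_aggregate_of_identical_reports_is_the_report():
    r = {"dice_pre_mean": 0.5, "dice_post_mean": 0.8, "tre_pre_mm": 2.0,
         "tre_post_mm": 1.0, "folding_fraction": 0.0}
    agg = aggregate_reports([dict(r), dict(r), dict(r)])
    assert agg["n_cases"] == 3
    assert agg["dice_post_mean_mean"] == pytest.approx(0.8)
    assert agg["dice_post_mean_sd"] == pytest.approx(0.0)


def test_landmark_csv_round_trip(tmp_path):
    pts = LandmarkSet(np.array([[1.5, 2.5, 10.0], [3.0, 4.0, 5.0]]),
                      ["left_bone", "right_bone"])
    pts.save_csv(tmp_path / "lm.csv")
    back = LandmarkSet.load_csv(tmp_path / "lm.csv")
    np.testing.assert_allclose(back.points, pts.points)
    assert back.labels == pts.labels
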