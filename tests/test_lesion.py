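"""Axial projection, spared fractions and slicewise alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordmotor.lesion import (
    LesionStudy,
    SlicewiseTransform,
    compute_spared_fraction,
    project_lesion_axial,
    slicewise_align,
    spared_profile,
)
from cordmotor.synthetic import make_region_atlas


def _study_from_lesion(cord2d, lesion2d_per_slice):
    nz = len(lesion2d_per_slice)
    cord = np.repeat(cord2d[:, :, None], nz, axis=2)
    lesion = np.stack(lesion2d_per_slice, axis=2) & cord
    return LesionStudy(cord_mask=cord, lesion_mask=lesion)


class TestProjection:
    def test_single_voxel_projects_to_single_pixel(self, small_atlas):
        cord2d = small_atlas.cord_mask_2d
        slices = [np.zeros((16, 16), bool) for _ in range(4)]
        slices[2][8, 7] = True
        proj = project_lesion_axial(_study_from_lesion(cord2d, slices))
        assert proj.sum() == 1 and proj[8, 7]

    def test_projection_is_idempotent_union(self, small_atlas):
        cord2d = small_atlas.cord_mask_2d
        col = np.zeros((16, 16), bool)
        col[8, 7] = True
        proj = project_lesion_axial(_study_from_lesion(cord2d, [col] * 4))
        assert proj.sum() == 1

    def test_disjoint_slices_project_to_union(self, small_atlas):
        cord2d = small_atlas.cord_mask_2d
        s2 = np.zeros((16, 16), bool)
        s2[6:8, 7] = True
        s7 = np.zeros((16, 16), bool)
        s7[9, 6:9] = True
        slices = [np.zeros((16, 16), bool) for _ in range(8)]
        slices[2], slices[7] = s2, s7
        study = _study_from_lesion(cord2d, slices)
        proj = project_lesion_axial(study)
        # brute-force union over voxels
        expected = np.zeros((16, 16), bool)
        for z in range(8):
            expected |= study.lesion_mask[:, :, z]
        assert np.array_equal(proj, expected)
        assert proj.sum() == s2.sum() + s7.sum()

    @settings(deadline=None, max_examples=25)
    @given(st.randoms(use_true_random=False))
    def test_projection_invariant_to_slice_permutation_and_duplication(self, small_atlas, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**31))
        cord2d = small_atlas.cord_mask_2d
        slices = [(rng.random((16, 16)) < 0.05) & cord2d for _ in range(5)]
        base = project_lesion_axial(_study_from_lesion(cord2d, slices))
        order = rng.permutation(5)
        permuted = project_lesion_axial(_study_from_lesion(cord2d, [slices[i] for i in order]))
        duplicated = project_lesion_axial(_study_from_lesion(cord2d, slices + [slices[0]]))
        assert np.array_equal(base, permuted)
        assert np.array_equal(base, duplicated)


class TestSparedFraction:
    def test_empty_lesion_is_fully_spared(self):
        w = np.ones((4, 4))
        assert compute_spared_fraction(np.zeros((4, 4), bool), w) == 100.0

    def test_full_coverage_is_zero_spared(self):
        w = np.zeros((4, 4))
        w[1:3, 1:3] = 1.0
        lesion = w > 0
        assert compute_spared_fraction(lesion, w) == 0.0

    def test_weighted_arithmetic(self):
        w = np.zeros((2, 5))
        w[0] = [1, 2, 3, 2, 2]  # total 10
        lesion = np.zeros((2, 5), bool)
        lesion[0, 1] = lesion[0, 3] = True  # covers weight 4
        assert compute_spared_fraction(lesion, w) == pytest.approx(60.0)

    def test_zero_weight_region_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            compute_spared_fraction(np.zeros((3, 3), bool), np.zeros((3, 3)))


class TestSparedProfile:
    def test_whole_cord_lesion_gives_all_zero(self, small_atlas):
        cord2d = small_atlas.cord_mask_2d
        study = _study_from_lesion(cord2d, [cord2d] * 3)
        assert spared_profile(study, small_atlas).as_array().tolist() == [0.0] * 5

    def test_left_half_lesion(self, circle_atlas):
        """Left-half lesion: left 0%, right 100%, A/P split by pixel count."""
        cord2d = circle_atlas.cord_mask_2d
        ix = np.arange(24)[:, None] * np.ones((1, 24))
        left_half = (ix >= 12) & cord2d  # +x is the subject's left
        study = _study_from_lesion(cord2d, [left_half] * 3)
        prof = spared_profile(study, circle_atlas)
        assert prof.spared_left == 0.0
        assert prof.spared_right == 100.0
        for name in ("anterior", "posterior"):
            w = circle_atlas.region_weights[name] > 0
            expected = 100.0 * (w & ~left_half).sum() / w.sum()
            assert getattr(prof, f"spared_{name}") == pytest.approx(expected)
        assert prof.spared_total == pytest.approx(100.0 * (cord2d & ~left_half).sum() / cord2d.sum())

    def test_lesion_outside_cord_rejected(self):
        cord = np.zeros((6, 6, 2), bool)
        cord[2:4, 2:4] = True
        lesion = np.zeros((6, 6, 2), bool)
        lesion[0, 0, 0] = True
        with pytest.raises(ValueError, match="contained"):
            LesionStudy(cord_mask=cord, lesion_mask=lesion)


class TestSlicewiseAlign:
    def test_identical_cord_gives_identity(self, circle_atlas):
        cord2d = circle_atlas.cord_mask_2d
        study = _study_from_lesion(cord2d, [np.zeros((24, 24), bool)] * 2)
        aligned, transforms = slicewise_align(study, cord2d)
        for tr in transforms:
            assert tr == SlicewiseTransform(0.0, 0.0, 1.0)
        assert np.array_equal(aligned.cord_mask, study.cord_mask)

    def test_translation_recovered(self):
        template = make_region_atlas((32, 32), (6.0, 6.0)).cord_mask_2d
        shifted = np.roll(np.roll(template, 3, axis=0), -2, axis=1)
        study = LesionStudy(
            cord_mask=shifted[:, :, None], lesion_mask=np.zeros_like(shifted)[:, :, None]
        )
        aligned, (tr,) = slicewise_align(study, template)
        assert (tr.dx, tr.dy) == pytest.approx((-3.0, 2.0))
        assert tr.scale == pytest.approx(1.0)
        assert np.array_equal(aligned.cord_mask[:, :, 0], template)

    def test_dilated_cord_scale_recovered(self):
        big = make_region_atlas((40, 40), (12.0, 12.0)).cord_mask_2d
        template = make_region_atlas((40, 40), (8.4852814,) * 2).cord_mask_2d
        study = LesionStudy(cord_mask=big[:, :, None], lesion_mask=np.zeros_like(big)[:, :, None])
        aligned, (tr,) = slicewise_align(study, template)
        # doubled area -> per-axis scale 1/sqrt(2), area matched within rounding
        assert tr.scale == pytest.approx(1 / np.sqrt(2), rel=0.05)
        assert aligned.cord_mask.sum() == pytest.approx(template.sum(), rel=0.05)

    def test_empty_slice_gets_identity(self, circle_atlas):
        cord2d = circle_atlas.cord_mask_2d
        cord = np.stack([cord2d, np.zeros_like(cord2d)], axis=2)
        study = LesionStudy(cord_mask=cord, lesion_mask=np.zeros_like(cord))
        _, transforms = slicewise_align(study, cord2d)
        assert transforms[1] == SlicewiseTransform(0.0, 0.0, 1.0)
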