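"""Statistical and structural guarantees of the synthetic generator."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from smallseg.phantom import (ALLOWED_N_SLICES, LesionSpec, PhantomSpec,
                              add_hyperintensity_speckles,
                              generate_brats_like_case, generate_cohort,
                              generate_phantom, generate_toy_canonical,
                              sample_lesion_spec)
from smallseg.preprocess import (SMALL_TUMOR_CM2, classify_tumor_size,
                                 max_slice_area_cm2, modality_lut)


def _spec(**kw):
    kw.setdefault("seed", 1)
    return PhantomSpec(in_plane_size=128, n_slices=48, **kw)


class TestGeneratePhantom:
    def test_no_lesion_gives_empty_mask(self):
        case = generate_phantom(_spec())
        assert case.truth_mask.sum() == 0
        assert case.group == "normal_plain"

    def test_deterministic_per_seed(self):
        a = generate_phantom(_spec(seed=9))
        b = generate_phantom(_spec(seed=9))
        np.testing.assert_array_equal(a.series.volume(), b.series.volume())
        np.testing.assert_array_equal(a.truth_mask, b.truth_mask)
        c = generate_phantom(_spec(seed=10))
        assert not np.array_equal(a.series.volume(), c.series.volume())

    def test_median_sized_small_lesion_classifies_small(self):
        # radii chosen so the equatorial slice area is about 1.1 cm^2
        r = np.sqrt(1.1 * 100.0 / np.pi)       # ~5.9 mm
        lesion = LesionSpec(center_voxel=(64, 64, 24), radii_mm=(r, r, 8.0),
                            size_class="small")
        case = generate_phantom(_spec(lesions=[lesion]))
        assert classify_tumor_size(case.truth_mask, 0.9) == "small"
        area = max_slice_area_cm2(case.truth_mask, 0.9)
        assert area == pytest.approx(1.1, rel=0.15)

    def test_invalid_slice_count_names_allowed_set(self):
        with pytest.raises(ValueError, match="24"):
            PhantomSpec(n_slices=30)
        assert ALLOWED_N_SLICES == {24, 25, 47, 48, 49, 50, 51}

    def test_metadata_round_trip(self):
        case = generate_phantom(_spec(seed=3))
        raw = case.series.volume().astype(np.float64)
        meta = case.series.slices[0][1]
        physical = modality_lut(raw, meta.rescale_slope, meta.rescale_intercept)
        recovered = (physical - meta.rescale_intercept) / meta.rescale_slope
        np.testing.assert_allclose(recovered, raw, atol=1e-9)

    def test_annotations_cover_exactly_foreground_slices(self, small_tumor_case):
        case = small_tumor_case
        fg = {i for i in range(case.truth_mask.shape[-1])
              if case.truth_mask[..., i].any()}
        ann = {i for i, uid in enumerate(case.series.uids())
               if uid in case.annotations.entries}
        assert fg == ann and len(fg) > 0


class TestLesionSampling:
    def test_size_class_guarantee_100_random_specs(self):
        spec = _spec()
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = sample_lesion_spec(rng, "small", spec)
            assert s.equatorial_area_cm2() < SMALL_TUMOR_CM2
        for _ in range(100):
            l = sample_lesion_spec(rng, "large", spec)
            assert l.equatorial_area_cm2() >= SMALL_TUMOR_CM2

    @pytest.mark.parametrize("size_class", ["small", "large"])
    def test_rendered_masks_respect_class(self, size_class):
        rng = np.random.default_rng(17)
        for k in range(4):
            spec = _spec(seed=50 + k)
            lesion = sample_lesion_spec(rng, size_class, spec)
            case = generate_phantom(replace(spec, lesions=[lesion]))
            assert classify_tumor_size(case.truth_mask,
                                       spec.pixel_spacing_mm) == size_class

    def test_invalid_lesions_rejected(self):
        with pytest.raises(ValueError):
            LesionSpec((0, 0, 0), (0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            LesionSpec((0, 0, 0), (1.0, 1.0, 1.0), intensity_boost=0.9)


class TestSpeckles:
    def test_zero_count_is_identity(self, normal_case):
        out = add_hyperintensity_speckles(normal_case, 0, seed=0)
        assert out is normal_case
        assert out.group == "normal_plain"

    def test_exact_component_count_added_mask_untouched(self, normal_case):
        count = 3
        out = add_hyperintensity_speckles(normal_case, count, seed=2)
        diff = out.series.volume() != normal_case.series.volume()
        _, n = ndimage.label(diff, structure=np.ones((3, 3, 3)))
        assert n == count
        assert out.truth_mask.sum() == 0
        assert out.group == "normal_hyperintense"
        # each speckle stays under 0.3 cm^2 per slice
        spacing = normal_case.series.pixel_spacing_mm
        lab, n2 = ndimage.label(diff, structure=np.ones((3, 3, 3)))
        for i in range(1, n2 + 1):
            per_slice = (lab == i).sum(axis=(0, 1)).max()
            assert per_slice * spacing ** 2 / 100.0 < 0.3

    def test_tumor_case_rejected(self, small_tumor_case):
        with pytest.raises(ValueError, match="normal"):
            add_hyperintensity_speckles(small_tumor_case, 2, seed=0)


class TestBratsLike:
    def test_label_support_and_blank_leading_slices(self):
        image, label = generate_brats_like_case(size=64, n_slices=155, seed=4)
        assert set(np.unique(label)) <= {0, 1, 2, 4}
        assert {1, 2, 4} <= set(np.unique(label))
        assert label[..., :15].sum() == 0 and np.abs(image[..., :15]).max() == 0

    def test_deterministic(self):
        a = generate_brats_like_case(size=48, n_slices=40, seed=8)
        b = generate_brats_like_case(size=48, n_slices=40, seed=8)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_thin_rejected(self):
        with pytest.raises(ValueError):
            generate_brats_like_case(size=48, n_slices=20)


class TestCohort:
    def test_group_counts_and_class_by_construction(self):
        cases = generate_cohort(2, 3, 2, 1, seed=0, in_plane_size=96)
        groups = [c.group for c in cases]
        assert groups.count("large_tumor") == 2
        assert groups.count("small_tumor") == 3
        assert groups.count("normal_plain") == 2
        assert groups.count("normal_hyperintense") == 1
        for c in cases:
            expected = {"large_tumor": "large", "small_tumor": "small"}.get(
                c.group, "none")
            assert classify_tumor_size(c.truth_mask,
                                       c.series.pixel_spacing_mm) == expected
            assert c.series.n_slices in ALLOWED_N_SLICES

    def test_empty_cohort(self):
        assert generate_cohort(0, 0, 0, 0, seed=0) == []

    def test_two_small_cases_both_small(self):
        cases = generate_cohort(0, 2, 0, 0, seed=3, in_plane_size=96)
        for c in cases:
            assert classify_tumor_size(c.truth_mask,
                                       c.series.pixel_spacing_mm) == "small"

    def test_deterministic_per_cohort_seed(self):
        a = generate_cohort(1, 1, 0, 0, seed=5, in_plane_size=96)
        b = generate_cohort(1, 1, 0, 0, seed=5, in_plane_size=96)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.series.volume(), cb.series.volume())


class TestToyCanonical:
    def test_classes_and_range(self):
        for cls in ("small", "large", "none"):
            case = generate_toy_canonical((32, 32, 32), cls, seed=2)
            assert case.size_class == cls
            assert 0.0 <= case.image.min() and case.image.max() <= 1.0

    def test_deterministic(self):
        a = generate_toy_canonical((32, 32, 32), "small", seed=6)
        b = generate_toy_canonical((32, 32, 32), "small", seed=6)
        np.testing.assert_array_equal(a.image, b.image)
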