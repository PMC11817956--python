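"""The DICOM grayscale chain and the canonicalization geometry ops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smallseg.metrics import dice
from smallseg.preprocess import (AnnotationSet, classify_tumor_size,
                                 decimate_slices, interpolate_slices,
                                 merge_brats_labels, modality_lut,
                                 pad_to_depth, preprocess_brats_case,
                                 preprocess_chgh_case, presentation_normalize,
                                 rasterize_annotations, resample_inplane,
                                 voi_lut)


class TestModalityLUT:
    @pytest.mark.parametrize("v, m, b0, expected", [
        (7, 1, 0, 7),
        (0, 3, -2, -2),
        (100, 2, 10, 210),
    ])
    def test_affine_map(self, v, m, b0, expected):
        assert modality_lut(v, m, b0) == expected


class TestVoiLUT:
    def test_boundary_values(self):
        c, w, gm = 100.0, 40.0, 4095
        assert voi_lut(c - w, c, w, gm) == 0.0           # far below window
        assert voi_lut(c, c, w, gm) == gm / 2            # window midpoint
        assert voi_lut(c + w, c, w, gm) == gm            # far above window
        # edges fall on the linear ramp, so the map is continuous
        assert voi_lut(c - w / 2, c, w, gm) == 0.0
        assert voi_lut(c + w / 2, c, w, gm) == gm

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            voi_lut(0.0, 0.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(c=st.floats(-500, 500), w=st.floats(1.0, 1000.0),
           gm=st.integers(1, 4095))
    def test_monotone_and_matches_piecewise_oracle(self, c, w, gm):
        v = np.linspace(c - w, c + w, 41)
        out = voi_lut(v, c, w, gm)
        assert np.all(np.diff(out) >= -1e-9)

        def oracle(x):  # direct per-element evaluation of the window map
            if x < c - w / 2:
                return 0.0
            if x > c + w / 2:
                return float(gm)
            return gm / w * (x + w / 2 - c)

        np.testing.assert_allclose(out, [oracle(x) for x in v],
                                   rtol=1e-9, atol=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(m=st.floats(0.1, 10), b0=st.floats(-1000, 1000),
           c=st.floats(-500, 500), w=st.floats(1.0, 1000.0))
    def test_composite_raw_to_12bit_map_is_monotone(self, m, b0, c, w):
        raw = np.linspace(0, 4095, 64)
        out = presentation_normalize(voi_lut(modality_lut(raw, m, b0), c, w))
        assert np.all(np.diff(out) >= 0)


class TestPresentationLUT:
    def test_constant_input_maps_to_zero(self):
        out = presentation_normalize(np.full((4, 4), 7.0))
        assert np.all(out == 0)

    def test_unit_range_maps_to_full_12bit(self):
        np.testing.assert_array_equal(
            presentation_normalize(np.array([0.0, 1.0])), [0, 4095])

    def test_output_bounded_and_integer(self):
        out = presentation_normalize(np.random.default_rng(0).random((8, 8)))
        assert out.dtype.kind == "i"
        assert out.min() == 0 and out.max() == 4095


class TestDecimation:
    def test_default_picks_every_other_slice_from_16(self):
        vol = np.arange(155)[None, None, :] * np.ones((2, 2, 1))
        out = decimate_slices(vol)
        assert out.shape[-1] == 64
        assert out[0, 0, 0] == 16 and out[0, 0, -1] == 142
        np.testing.assert_array_equal(out[0, 0], 16 + 2 * np.arange(64))

    def test_single_slice_and_small_volume(self):
        vol = np.arange(10)[None, None, :] * np.ones((1, 1, 1))
        np.testing.assert_array_equal(
            decimate_slices(vol, start=3, count=1)[0, 0], [3])
        np.testing.assert_array_equal(
            decimate_slices(vol, start=0, count=5)[0, 0], [0, 2, 4, 6, 8])

    def test_out_of_range_names_bound(self):
        with pytest.raises(ValueError, match="142"):
            decimate_slices(np.zeros((2, 2, 100)))


class TestLabelMerge:
    def test_quoted_rule(self):
        np.testing.assert_array_equal(
            merge_brats_labels(np.array([0, 1, 2, 4])), [0, 1, 1, 1])

    def test_all_zero_stays_zero(self):
        assert merge_brats_labels(np.zeros((3, 3), dtype=int)).sum() == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from([0, 1, 2, 4]), min_size=1, max_size=64))
    def test_foreground_count_conserved(self, values):
        arr = np.array(values)
        merged = merge_brats_labels(arr)
        assert merged.sum() == np.isin(arr, [1, 2, 4]).sum()

    def test_unexpected_value_listed(self):
        with pytest.raises(ValueError, match="3"):
            merge_brats_labels(np.array([0, 3]))


class TestRasterize:
    def test_square_polygon_fill_bounds(self):
        square = np.array([[5, 5], [5, 14], [14, 14], [14, 5], [5, 5]], float)
        mask = rasterize_annotations([(square, 1.0)], (32, 32))
        assert 100 <= mask.sum() <= 144

    def test_empty_and_degenerate(self):
        assert rasterize_annotations([], (8, 8)).sum() == 0
        with pytest.warns(UserWarning, match="degenerate"):
            mask = rasterize_annotations([(np.array([[1, 1], [2, 2]], float), 1.0)],
                                         (8, 8))
        assert mask.sum() == 0

    def test_fill_matches_even_odd_point_in_polygon_oracle(self):
        from matplotlib.path import Path

        rng = np.random.default_rng(3)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 7))
        pts = np.stack([16 + 10 * np.cos(angles), 16 + 10 * np.sin(angles)], 1)
        mask = rasterize_annotations([(pts, 1.0)], (32, 32))
        yy, xx = np.mgrid[0:32, 0:32]
        oracle = Path(pts).contains_points(
            np.stack([yy.ravel(), xx.ravel()], 1)).reshape(32, 32)
        assert dice(mask, oracle).dice >= 0.9

    def test_lesion_contours_round_trip(self, small_tumor_case):
        case = small_tumor_case
        shape2d = case.truth_mask.shape[:2]
        for i, uid in enumerate(case.series.uids()):
            if uid in case.annotations.entries:
                mask = rasterize_annotations(case.annotations.entries[uid],
                                             shape2d)
                assert dice(mask, case.truth_mask[..., i]).dice >= 0.9


class TestSliceInterpolation:
    def test_24_to_47_and_25_to_48(self):
        assert interpolate_slices(np.zeros((4, 4, 24))).shape[-1] == 47
        assert interpolate_slices(np.zeros((4, 4, 25))).shape[-1] == 48

    def test_originals_reproduced_at_even_indices(self):
        rng = np.random.default_rng(0)
        vol = rng.random((5, 5, 24))
        out = interpolate_slices(vol)
        np.testing.assert_allclose(out[..., ::2], vol, atol=1e-9)

    def test_constant_volume_stays_constant(self):
        out = interpolate_slices(np.full((3, 3, 24), 2.5))
        np.testing.assert_allclose(out, 2.5)

    def test_other_depths_pass_through(self):
        vol = np.random.default_rng(1).random((3, 3, 30))
        assert interpolate_slices(vol) is vol

    def test_label_rebinarized(self):
        lab = np.zeros((4, 4, 24), dtype=np.uint8)
        lab[1:3, 1:3, 10:14] = 1
        _, out = interpolate_slices(np.zeros((4, 4, 24)), lab)
        assert set(np.unique(out)) <= {0, 1}
        assert out.sum() >= lab.sum()


class TestPadding:
    def test_pad_appends_zero_slices(self):
        vol = np.ones((3, 3, 47))
        out = pad_to_depth(vol)
        assert out.shape[-1] == 64
        assert out[..., 47:].sum() == 0
        assert out.sum() == vol.sum()          # foreground conserved

    def test_full_depth_unchanged_and_overfull_rejected(self):
        vol = np.ones((2, 2, 64))
        assert pad_to_depth(vol) is vol
        with pytest.raises(ValueError):
            pad_to_depth(np.ones((2, 2, 65)))


class TestResample:
    def test_shape_contract_and_constant(self):
        checker = np.indices((256, 256, 4)).sum(axis=0) % 2
        out = resample_inplane(checker.astype(float))
        assert out.shape == (128, 128, 4)
        np.testing.assert_allclose(resample_inplane(np.full((64, 64, 2), 3.0)), 3.0)

    @pytest.mark.parametrize("side", [2, 3, 4, 6])
    def test_small_labels_survive_downsampling(self, side):
        lab = np.zeros((256, 256, 2), dtype=np.uint8)
        lab[100:100 + side, 100:100 + side, :] = 1
        _, out = resample_inplane(np.zeros((256, 256, 2)), lab)
        assert set(np.unique(out)) <= {0, 1}
        assert out.sum() > 0


class TestSizeClass:
    def test_empty_small_large(self):
        lab = np.zeros((64, 64, 3), dtype=np.uint8)
        assert classify_tumor_size(lab, 1.0) == "none"
        lab[:10, :10, 1] = 1                        # 100 px @ 1 mm = 1.0 cm^2
        assert classify_tumor_size(lab, 1.0) == "small"
        lab[:20, :20, 2] = 1                        # 400 px = 4.0 cm^2 max slice
        assert classify_tumor_size(lab, 1.0) == "large"


class TestFullChains:
    def test_chgh_chain_small_case(self, small_tumor_case):
        case = small_tumor_case
        cc = preprocess_chgh_case(case.series, case.annotations, source_id="x")
        assert cc.image.shape == (128, 128, 64)
        assert cc.label.shape == (128, 128, 64)
        assert cc.size_class == "small"
        assert 0.0 <= cc.image.min() and cc.image.max() <= 1.0
        assert cc.label.sum() > 0

    def test_chgh_chain_normal_case(self, normal_case):
        cc = preprocess_chgh_case(normal_case.series, normal_case.annotations)
        assert cc.label.sum() == 0
        assert cc.size_class == "none"

    def test_chgh_chain_deterministic(self, small_tumor_case):
        case = small_tumor_case
        a = preprocess_chgh_case(case.series, case.annotations)
        b = preprocess_chgh_case(case.series, case.annotations)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.label, b.label)

    def test_thin_stack_is_interpolated(self):
        from dataclasses import replace

        from smallseg.phantom import PhantomSpec, generate_phantom, sample_lesion_spec
        spec = PhantomSpec(in_plane_size=128, n_slices=24, seed=5)
        lesion = sample_lesion_spec(np.random.default_rng(5), "small", spec)
        case = generate_phantom(replace(spec, lesions=[lesion]))
        cc = preprocess_chgh_case(case.series, case.annotations)
        assert cc.image.shape == (128, 128, 64)
        # 24 -> 47 interpolated slices, then zero padding to 64
        assert np.abs(cc.image[..., 47:]).max() == 0

    def test_orphan_annotation_uid_rejected(self, small_tumor_case):
        case = small_tumor_case
        bad = AnnotationSet(entries={**case.annotations.entries,
                                     "no-such-uid": []})
        with pytest.raises(ValueError, match="no-such-uid"):
            preprocess_chgh_case(case.series, bad)

    def test_brats_chain(self):
        from smallseg.phantom import generate_brats_like_case
        image, label = generate_brats_like_case(size=96, n_slices=155, seed=2)
        cc = preprocess_brats_case(image, label)
        assert cc.image.shape == (128, 128, 64)
        assert set(np.unique(cc.label)) <= {0, 1}

    def test_brats_all_background(self):
        cc = preprocess_brats_case(np.zeros((64, 64, 155)),
                                   np.zeros((64, 64, 155), dtype=np.uint8))
        assert cc.label.sum() == 0 and cc.size_class == "none"

    def test_nifti_round_trip(self, tmp_path, small_tumor_case):
        from smallseg.preprocess import load_canonical_nifti, save_canonical_nifti
        case = small_tumor_case
        cc = preprocess_chgh_case(case.series, case.annotations)
        save_canonical_nifti(cc, tmp_path / "i.nii.gz", tmp_path / "l.nii.gz")
        back = load_canonical_nifti(tmp_path / "i.nii.gz", tmp_path / "l.nii.gz")
        np.testing.assert_array_equal(back.label, cc.label)
        np.testing.assert_allclose(back.image, cc.image, atol=1e-7)
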