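"""Unit and property tests for the segmentation/overlap pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from neuroassay import imaging as im

PARAMS = im.SegmentationParams(thresholds={})


def mask(arr):
    return im.BinaryMask(np.asarray(arr, bool))


class TestPreprocess:
    def test_endpoints_map_to_0_and_255(self):
        raster = np.array([[0, 100], [50, 100]], float)
        out = im.preprocess(raster, PARAMS)
        assert out.min() == 0 and out.max() == 255

    def test_midpoint_with_default_gamma(self):
        raster = np.array([[0.0, 0.5, 1.0]])
        out = im.preprocess(raster, PARAMS)
        assert out[0, 1] == round(255 * 0.5 ** 0.8) == 146

    def test_gamma_one_is_plain_minmax_rescale(self):
        raster = np.array([[10.0, 20.0, 30.0]])
        p = im.SegmentationParams(thresholds={}, gamma=1.0)
        assert im.preprocess(raster, p).tolist() == [[0, 128, 255]]

    def test_constant_images_map_to_zeros(self):
        for value in (0.0, 7.0):
            out = im.preprocess(np.full((4, 4), value), PARAMS)
            assert not out.any()

    def test_resize_applied_before_normalization(self):
        p = im.SegmentationParams(thresholds={}, resize_factor=0.5)
        out = im.preprocess(np.arange(64, dtype=float).reshape(8, 8), p)
        assert out.shape == (4, 4)

    @settings(derandomize=True, max_examples=30)
    @given(hnp.arrays(np.uint16, (6, 6), elements=st.integers(0, 65535)))
    def test_mapping_is_order_preserving(self, raster):
        out = im.preprocess(raster, PARAMS).ravel().astype(int)
        flat = raster.ravel().astype(int)
        for i in range(len(flat)):
            for j in range(len(flat)):
                if flat[i] < flat[j]:
                    assert out[i] <= out[j]


class TestSegment:
    def test_threshold_255_gives_empty_mask(self):
        assert im.segment(np.full((5, 5), 255, np.uint8), 255).area_px == 0

    def test_threshold_0_on_binary_image_keeps_255_pixels(self):
        img = np.zeros((4, 4), np.uint8)
        img[0, :2] = 255
        assert im.segment(img, 0).area_px == 2

    def test_counts_match_constructed_fixture(self):
        img = np.zeros((10, 10), np.uint8)
        img.ravel()[:25] = 200
        assert im.segment(img, 128).area_px == 25

    def test_strictness_is_greater_than(self):
        img = np.full((3, 3), 100, np.uint8)
        assert im.segment(img, 100).area_px == 0
        assert im.segment(img, 100, strict=False).area_px == 9

    @pytest.mark.parametrize("threshold", [0, 1, 100, 254])
    def test_rendered_mask_resegmentation_is_idempotent(self, threshold):
        rng = np.random.default_rng(0)
        m = rng.random((16, 16)) > 0.6
        rendered = (m * 255).astype(np.uint8)
        assert np.array_equal(im.segment(rendered, threshold).pixels, m)

    def test_raising_threshold_never_grows_area(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (32, 32), np.uint8)
        areas = [im.segment(img, t).area_px for t in range(0, 256, 5)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestAreasAndOverlap:
    def test_percent_area_boundaries_and_count(self):
        assert im.percent_area(mask(np.zeros((10, 10)))) == 0.0
        assert im.percent_area(mask(np.ones((10, 10)))) == 100.0
        m = np.zeros((10, 10), bool)
        m.ravel()[:25] = True
        assert im.percent_area(mask(m)) == 25.0

    def test_merged_is_union_or_verbatim_passthrough(self):
        a = np.zeros((6, 6), bool); a.ravel()[:10] = True
        b = np.zeros((6, 6), bool); b.ravel()[10:30] = True
        union = im.merged_area([mask(a), mask(b)])
        assert union.area_px == 30
        provided = mask(np.ones((6, 6)))
        assert im.merged_area([mask(a)], provided) is provided
        assert im.merged_area([mask(a)]).area_px == 10

    def test_merged_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            im.merged_area([mask(np.zeros((4, 4))), mask(np.zeros((5, 5)))])

    def test_overlap_metrics_hand_case(self):
        t = np.zeros((20, 20), bool); t.ravel()[:40] = True
        o = np.zeros((20, 20), bool); o.ravel()[30:80] = True   # AND = 10
        merged = np.zeros((20, 20), bool); merged.ravel()[:200] = True
        res = im.overlap_metrics(mask(t), mask(o), mask(merged))
        assert res == {"overlap_pct_merged": 5.0,
                       "overlap_pct_target": 25.0, "and_area_px": 10}

    def test_overlap_identity_and_disjoint(self):
        t = np.zeros((6, 6), bool); t.ravel()[:9] = True
        res = im.overlap_metrics(mask(t), mask(t), mask(t))
        assert res["overlap_pct_target"] == 100.0
        o = np.zeros((6, 6), bool); o.ravel()[9:12] = True
        res = im.overlap_metrics(mask(t), mask(o), im.merged_area([mask(t), mask(o)]))
        assert res["overlap_pct_merged"] == res["overlap_pct_target"] == 0.0

    def test_zero_denominators_flag_nan_not_zero(self):
        empty = mask(np.zeros((4, 4)))
        full = mask(np.ones((4, 4)))
        res = im.overlap_metrics(empty, full, empty)
        assert np.isnan(res["overlap_pct_merged"])
        assert np.isnan(res["overlap_pct_target"])


class TestMembership:
    def test_counts_and_legend(self):
        a = np.zeros((4, 4), bool); a[0, 0] = a[1, 1] = True
        b = np.zeros((4, 4), bool); b[0, 0] = True
        c = np.zeros((4, 4), bool); c[0, 0] = True
        mm = im.membership_map([mask(a), mask(b), mask(c)])
        assert mm.counts[0, 0] == 3 and mm.counts[1, 1] == 1
        assert set(mm.legend) == {2, 3}
        rgb = im.membership_to_rgb(mm)
        assert tuple(rgb[0, 0]) == mm.legend[3]

    def test_empty_masks_give_zero_counts(self):
        mm = im.membership_map([mask(np.zeros((3, 3)))] * 2)
        assert not mm.counts.any()

    def test_mask_count_limits(self):
        with pytest.raises(ValueError):
            im.membership_map([mask(np.zeros((3, 3)))])
        with pytest.raises(ValueError):
            im.membership_map([mask(np.zeros((3, 3)))] * 5)


class TestLiveDead:
    @staticmethod
    def _raster(pct):
        img = np.zeros((10, 10), np.uint8)
        img.ravel()[:pct] = 255
        return img

    def test_ratio_of_percent_areas(self):
        p = im.SegmentationParams(thresholds={"green": 128, "red": 128})
        res = im.live_dead_ratio(self._raster(20), self._raster(10), p)
        assert res.ratio == pytest.approx(2.0)
        assert (res.green_pct, res.red_pct) == (20.0, 10.0)

    def test_identical_channels_give_unity(self):
        p = im.SegmentationParams(thresholds={"green": 128, "red": 128})
        res = im.live_dead_ratio(self._raster(15), self._raster(15), p)
        assert res.ratio == 1.0

    def test_zero_dead_area_flags_undefined(self):
        p = im.SegmentationParams(thresholds={"green": 128, "red": 128})
        res = im.live_dead_ratio(self._raster(15), np.zeros((10, 10), np.uint8), p)
        assert not res.defined and np.isnan(res.ratio)


class TestQuantifyAndAggregate:
    @staticmethod
    def _field(seed=0):
        rng = np.random.default_rng(seed)
        chans = {c: rng.integers(0, 256, (24, 24), np.uint8) for c in "ab"}
        return im.MultiChannelField(chans, field_id=f"f{seed}", well_id="w1")

    def test_same_field_same_params_identical_reports(self):
        p = im.SegmentationParams(thresholds={"a": 100, "b": 150})
        fld = self._field()
        assert im.quantify_field(fld, p).metrics() == \
            im.quantify_field(fld, p).metrics()

    def test_missing_threshold_is_an_error(self):
        with pytest.raises(ValueError, match="threshold"):
            im.quantify_field(self._field(), im.SegmentationParams(
                thresholds={"a": 100}))

    def test_provided_merged_mask_is_the_denominator(self):
        fld = self._field()
        fld.merged_mask = np.ones((24, 24), bool)
        p = im.SegmentationParams(thresholds={"a": 100, "b": 150})
        rep = im.quantify_field(fld, p)
        assert rep.merged_area_px == 24 * 24

    def test_aggregate_mean_and_sample_sd(self):
        reps = []
        for fid, pct in enumerate((10, 20, 30)):
            reps.append(im.AreaReport(f"f{fid}", "w1", 100,
                                      {"a": float(pct)}, {"a": 50.0}, {}, {}))
        summary = im.aggregate(reps)
        row = summary.table.set_index("metric").loc["area_pct_field/a"]
        assert row["mean"] == 20.0 and row["sd"] == pytest.approx(10.0)
        assert row["n"] == 3

    def test_aggregate_single_field_and_identical_fields(self):
        rep = im.AreaReport("f0", "w1", 10, {"a": 5.0}, {"a": 50.0}, {}, {})
        one = im.aggregate([rep]).table.set_index("metric")
        assert one.loc["area_pct_field/a", "mean"] == 5.0
        assert np.isnan(one.loc["area_pct_field/a", "sd"])
        same = im.aggregate([rep, rep]).table.set_index("metric")
        assert same.loc["area_pct_field/a", "sd"] == 0.0

    def test_aggregate_excludes_undefined_metrics_pairwise(self):
        r1 = im.AreaReport("f0", "w1", 10, {"a": 5.0}, {"a": np.nan}, {}, {})
        r2 = im.AreaReport("f1", "w1", 10, {"a": 15.0}, {"a": 40.0}, {}, {})
        tab = im.aggregate([r1, r2]).table.set_index("metric")
        assert tab.loc["area_pct_merged/a", "n"] == 1
        assert tab.loc["area_pct_merged/a", "mean"] == 40.0
        assert tab.loc["area_pct_field/a", "n"] == 2

    def test_aggregate_rejects_empty_and_mixed_wells(self):
        with pytest.raises(ValueError):
            im.aggregate([])
        r1 = im.AreaReport("f0", "w1", 1, {}, {}, {}, {})
        r2 = im.AreaReport("f1", "w2", 1, {}, {}, {}, {})
        with pytest.raises(ValueError):
            im.aggregate([r1, r2])
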