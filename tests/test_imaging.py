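"""Chart measurement, color-correction round trips, segmentation accuracy
and contour filtration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from grainaging.chart import build_chart_layout, render_chart
from grainaging.imaging import (
    ChartMissingError,
    ColorFitError,
    ColorTransform,
    ContourFilters,
    GrainContour,
    apply_color_correction,
    extract_grain_contours,
    fit_color_correction,
    locate_chart,
    segment_grains,
)


@pytest.fixture(scope="module")
def layout():
    return build_chart_layout(pitch_px=40, pitch_mm=4.0)


def chart_scene(layout, cast=None, h=420, w=420):
    img = np.full((h, w, 3), 250.0)
    render_chart(img, layout)
    if cast is not None:
        img = img @ np.asarray(cast).T
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


class TestLocateChart:
    def test_identity_cast_measures_references(self, layout):
        measured, mm = locate_chart(chart_scene(layout), layout)
        assert np.abs(measured - layout.reference_rgb).max() <= 1.0
        assert mm == pytest.approx(0.1)

    def test_erased_chart_raises(self, layout):
        img = np.full((420, 420, 3), 250, dtype=np.uint8)
        with pytest.raises(ChartMissingError):
            locate_chart(img, layout)


class TestColorCorrection:
    def test_identity_fit(self, layout):
        ref = layout.reference_rgb.astype(float)
        t = fit_color_correction(ref, ref)
        assert np.allclose(t.matrix[:, :3], np.eye(3), atol=1e-9)
        assert np.allclose(t.matrix[:, 3], 0, atol=1e-7)
        assert t.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_half_gain_recovered(self, layout):
        ref = layout.reference_rgb.astype(float)
        t = fit_color_correction(0.5 * ref, ref)
        assert np.allclose(np.diag(t.matrix[:, :3]), 2.0, atol=1e-6)

    def test_too_few_pairs(self):
        with pytest.raises(ColorFitError):
            fit_color_correction(np.eye(3), np.eye(3))

    def test_rank_deficient(self):
        same = np.tile([10.0, 20.0, 30.0], (6, 1))
        with pytest.raises(ColorFitError):
            fit_color_correction(same, same)

    def test_identity_transform_is_noop(self, layout):
        img = chart_scene(layout)
        out = apply_color_correction(img, ColorTransform.identity())
        assert np.array_equal(out, img)

    @pytest.mark.parametrize("gains", [(0.9, 1.0, 1.1), (1.05, 0.95, 1.0)])
    def test_cast_roundtrip_restores_patches(self, layout, gains):
        """Forward-simulate a diagonal cast, fit on the measured chart,
        apply: patch means return to reference within ±2."""
        img = chart_scene(layout, cast=np.diag(gains))
        measured, _ = locate_chart(img, layout)
        t = fit_color_correction(measured, layout.reference_rgb)
        corrected = apply_color_correction(img, t)
        measured2, _ = locate_chart(corrected, layout)
        assert np.abs(measured2 - layout.reference_rgb).max() <= 2.0

    @given(st.integers(0, 10**6))
    def test_random_cast_roundtrip(self, layout, seed):
        rng = np.random.default_rng(seed)
        cast = np.diag(rng.uniform(0.85, 1.1, 3))
        cast += rng.uniform(-0.03, 0.03, (3, 3))
        img = chart_scene(layout, cast=cast)
        measured, _ = locate_chart(img, layout)
        t = fit_color_correction(measured, layout.reference_rgb)
        corrected = apply_color_correction(img, t)
        measured2, _ = locate_chart(corrected, layout)
        assert np.abs(measured2 - layout.reference_rgb).max() <= 2.0

    def test_output_stays_in_byte_range(self, layout):
        img = chart_scene(layout)
        t = ColorTransform(np.hstack([np.eye(3) * 3.0, np.full((3, 1), -100.0)]))
        out = apply_color_correction(img, t)
        assert out.dtype == np.uint8
        assert out.min() >= 0 and out.max() <= 255


class TestSegmentation:
    def test_blank_image_gives_empty_mask(self, layout):
        img = np.full((300, 300, 3), 250, dtype=np.uint8)
        assert segment_grains(img).sum() == 0

    def test_chart_forced_to_background(self, layout, tiny_study):
        import imageio.v3 as iio

        path = tiny_study.design.image_path.iloc[0]
        mask = segment_grains(iio.imread(path), chart_bbox=layout.bbox)
        r0, c0, r1, c1 = layout.bbox
        assert not mask[r0:r1, c0:c1].any()

    def test_grain_recovery_iou(self, tiny_study, tiny_extraction):
        """Per-grain IoU vs generator masks >= 0.95 and counts match."""
        for item in tiny_extraction:
            truth = tiny_study.masks[item["image_id"]]
            assert len(item["contours"]) == len(truth)
            for c in item["contours"]:
                rr, cc = c.pixel_coords
                cm = np.zeros(truth[0].mask.shape, bool)
                cm[rr, cc] = True
                iou = max(
                    np.logical_and(cm, t.mask).sum()
                    / np.logical_or(cm, t.mask).sum()
                    for t in truth
                )
                assert iou >= 0.95


class TestContours:
    def _blob_mask(self, n=18, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.zeros((600, 800), bool)
        centers = []
        rr0, cc0 = np.mgrid[0:600, 0:800]
        for _ in range(n):
            while True:
                r, c = rng.uniform(40, 560), rng.uniform(40, 760)
                if all(np.hypot(r - a, c - b) > 45 for a, b in centers):
                    centers.append((r, c))
                    break
            mask |= (rr0 - r) ** 2 + (cc0 - c) ** 2 < 18**2
        return mask

    def test_disjoint_blobs_all_found(self):
        contours, rejected = extract_grain_contours(
            self._blob_mask(), ContourFilters(min_area_mm2=0, max_area_mm2=1e9)
        )
        assert len(contours) == 18
        assert rejected == []

    def test_small_blob_rejected_with_reason(self):
        mask = np.zeros((100, 100), bool)
        mask[40:60, 40:60] = True          # 400 px
        mask[10:13, 10:13] = True          # 9 px
        contours, rejected = extract_grain_contours(
            mask, ContourFilters(min_area_mm2=100, max_area_mm2=1e9)
        )
        assert len(contours) == 1
        assert [r.reason for r in rejected] == ["too_small"]

    def test_border_touching_excluded(self):
        mask = np.zeros((100, 100), bool)
        mask[0:20, 40:60] = True
        contours, rejected = extract_grain_contours(mask, ContourFilters())
        assert contours == []
        assert rejected[0].reason == "border"

    def test_hull_inequalities_exact(self, tiny_extraction):
        """Pc <= Ps and hull_area >= polygon area for every emitted contour."""
        checked = 0
        for item in tiny_extraction:
            for c in item["contours"]:
                assert c.hull_perimeter <= c.perimeter + 1e-9
                assert c.hull_area >= c.polygon_area - 1e-9
                checked += 1
        assert checked > 0

    def test_analytic_polygon_constructor_rejects_degenerate(self):
        with pytest.raises(ValueError):
            GrainContour.from_polygon([(0, 0), (1, 1), (2, 2)])
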