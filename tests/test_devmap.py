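"""Deviation-map quantification: parsing, ellipse fitting, Hough, extents."""

import numpy as np
import pytest
from skimage.draw import line as draw_line
from skimage.measure import EllipseModel

from macudev import (
    AnnulusSpec,
    DeviationCategory,
    DeviationMap,
    HoughConfig,
    RasterGeometry,
    extent_summary,
    fit_annulus,
    fit_ellipse_direct,
    parse_colors,
    remove_overlay_lines,
    render_deviation_map,
    sector_line_segments,
)
from macudev.core import DEFAULT_PALETTE, OVERLAY_RGB


def wnl_map(geom):
    return DeviationMap(
        np.full(geom.shape, int(DeviationCategory.WNL), dtype=np.int8), geom
    )


def geom_n(n, side_mm=7.2):
    return RasterGeometry((n, n), (side_mm / n, side_mm / n), ((n - 1) / 2,) * 2)


class TestParseColors:
    def test_uniform_green_is_all_wnl(self, geom64):
        img = np.zeros((*geom64.shape, 3), np.uint8)
        img[:] = DEFAULT_PALETTE[DeviationCategory.WNL]
        parsed = parse_colors(img, geometry=geom64)
        assert np.all(parsed.categories == int(DeviationCategory.WNL))
        assert extent_summary(parsed).pct == {
            "abn1": 0.0, "abn5": 0.0, "sup95": 0.0, "sup99": 0.0
        }

    def test_off_palette_colors_are_excluded(self, geom64):
        img = np.full((*geom64.shape, 3), 128, np.uint8)  # mid-gray
        parsed = parse_colors(img, geometry=geom64)
        assert np.all(parsed.categories == int(DeviationCategory.EXCLUDED))

    def test_ambiguous_palette_rejected(self, geom64):
        img = np.zeros((*geom64.shape, 3), np.uint8)
        close = dict(DEFAULT_PALETTE)
        close[DeviationCategory.ABNORMAL_1] = (34, 177, 90)  # near WNL green
        with pytest.raises(ValueError, match="ambiguous palette"):
            parse_colors(img, palette=close, tolerance=10)

    def test_within_tolerance_maps_to_nearest(self, geom64):
        img = np.zeros((*geom64.shape, 3), np.uint8)
        rgb = np.array(DEFAULT_PALETTE[DeviationCategory.SUPER_95])
        img[:] = np.clip(rgb + 5, 0, 255)
        parsed = parse_colors(img, geometry=geom64, tolerance=10)
        assert np.all(parsed.categories == int(DeviationCategory.SUPER_95))


class TestEllipseFit:
    def ellipse_points(self, cx, cy, a, b, n=300, theta=0.0, rng=None, noise=0.0):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = a * np.cos(t)
        y = b * np.sin(t)
        if theta:
            x, y = x * np.cos(theta) - y * np.sin(theta), x * np.sin(theta) + y * np.cos(theta)
        x, y = x + cx, y + cy
        if noise and rng is not None:
            x = x + rng.uniform(-noise, noise, n)
            y = y + rng.uniform(-noise, noise, n)
        return x, y

    def test_exact_points_recovered(self):
        x, y = self.ellipse_points(1.0, -2.0, 2.4, 2.0)
        cx, cy, a, b, theta = fit_ellipse_direct(x, y)
        assert (cx, cy, a, b) == pytest.approx((1.0, -2.0, 2.4, 2.0), abs=1e-9)

    def test_circle_symmetric(self):
        x, y = self.ellipse_points(0.0, 0.0, 1.5, 1.5)
        _, _, a, b, _ = fit_ellipse_direct(x, y)
        assert a == pytest.approx(b, abs=1e-9)

    def test_rotated_ellipse(self):
        x, y = self.ellipse_points(0.5, 0.5, 3.0, 1.0, theta=0.3)
        cx, cy, a, b, theta = fit_ellipse_direct(x, y)
        assert (cx, cy, a, b) == pytest.approx((0.5, 0.5, 3.0, 1.0), abs=1e-8)
        assert theta == pytest.approx(0.3, abs=1e-6)

    def test_agrees_with_skimage_on_noisy_points(self, rng):
        """Cross-check against an independent least-squares ellipse fitter."""
        x, y = self.ellipse_points(10.0, 20.0, 8.0, 5.0, n=400, rng=rng, noise=0.3)
        cx, cy, a, b, _ = fit_ellipse_direct(x, y)
        ref = EllipseModel.from_estimate(np.column_stack([x, y]))
        rcx, rcy = ref.center
        ra, rb = sorted(ref.axis_lengths, reverse=True)
        assert (cx, cy) == pytest.approx((rcx, rcy), abs=0.05)
        assert (max(a, b), min(a, b)) == pytest.approx((ra, rb), abs=0.05)

    def test_noisy_boundary_center_recovery(self, rng):
        """+/- 0.5 px boundary jitter, >= 200 points: center within 1 px."""
        for _ in range(20):
            x, y = self.ellipse_points(0.0, 0.0, 21.3, 17.8, n=250, rng=rng, noise=0.5)
            cx, cy, a, b, _ = fit_ellipse_direct(x, y)
            assert np.hypot(cx, cy) < 1.0
            assert (a, b) == pytest.approx((21.3, 17.8), abs=1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_ellipse_direct(np.arange(5.0), np.arange(5.0))


class TestFitAnnulus:
    def test_rendered_annulus_recovered_within_one_pitch(self):
        geom = geom_n(200)
        ann = AnnulusSpec(center_px=geom.fovea_px)
        img = render_deviation_map(
            wnl_map(geom), annulus=ann, sector_lines=sector_line_segments(ann, geom)
        )
        fit = fit_annulus(img, ann, geom)
        pitch = geom.pitch_mm[0]
        assert fit.outer_semiaxes_mm == pytest.approx((2.4, 2.0), abs=pitch)
        assert fit.inner_semiaxes_mm == pytest.approx((0.6, 0.5), abs=pitch)
        assert fit.center_px == pytest.approx(geom.fovea_px, abs=1.0)

    def test_offset_center_recovered(self):
        geom = geom_n(200)
        true = AnnulusSpec(center_px=(95.0, 103.0))
        img = render_deviation_map(wnl_map(geom), annulus=true)
        prior = AnnulusSpec(center_px=geom.fovea_px)  # prior center is wrong
        fit = fit_annulus(img, prior, geom, band_rel_width=0.25)
        assert fit.center_px == pytest.approx((95.0, 103.0), abs=1.0)

    def test_blank_map_rejected(self):
        geom = geom_n(64)
        img = render_deviation_map(wnl_map(geom))
        with pytest.raises(ValueError, match="boundary pixels"):
            fit_annulus(img, AnnulusSpec(center_px=geom.fovea_px), geom)


class TestRemoveOverlayLines:
    def test_single_drawn_line_excluded(self, geom64):
        geom = geom_n(128)
        rr, cc = draw_line(10, 5, 109, 104)  # 100-px diagonal
        mask = np.zeros(geom.shape, bool)
        mask[rr, cc] = True
        out = remove_overlay_lines(wnl_map(geom), candidate_mask=mask)
        excluded = out.categories == int(DeviationCategory.EXCLUDED)
        assert excluded[rr, cc].sum() >= 95
        assert (excluded & ~mask).sum() == 0  # non-line pixels untouched

    def test_no_lines_identity(self, geom64):
        devmap = wnl_map(geom64)
        out = remove_overlay_lines(devmap)
        assert np.array_equal(out.categories, devmap.categories)

    def test_two_perpendicular_lines_union_arithmetic(self):
        geom = geom_n(128)
        rr1, cc1 = draw_line(10, 5, 109, 104)
        rr2, cc2 = draw_line(64, 4, 64, 123)
        mask = np.zeros(geom.shape, bool)
        mask[rr1, cc1] = True
        mask[rr2, cc2] = True
        out = remove_overlay_lines(wnl_map(geom), candidate_mask=mask)
        n_excluded = int(np.sum(out.categories == int(DeviationCategory.EXCLUDED)))
        assert n_excluded == int(mask.sum())  # union = sum minus intersection

    def test_default_candidates_are_excluded_pixels(self):
        geom = geom_n(128)
        devmap = wnl_map(geom)
        rr, cc = draw_line(20, 20, 100, 100)
        devmap.categories[rr, cc] = int(DeviationCategory.EXCLUDED)
        out = remove_overlay_lines(devmap)
        assert np.array_equal(out.categories, devmap.categories)  # idempotent


class TestExtentSummary:
    def make_map(self, n=10):
        geom = RasterGeometry((n, n), (0.1, 0.1), ((n - 1) / 2,) * 2)
        return wnl_map(geom)

    def test_all_wnl_zero_extents(self):
        summ = extent_summary(self.make_map())
        assert all(v == 0.0 for v in summ.pct.values())
        assert summ.n_total_px == 100

    def test_seven_abnormal_pixels_seven_percent(self):
        devmap = self.make_map()
        devmap.categories.ravel()[:7] = int(DeviationCategory.ABNORMAL_1)
        assert extent_summary(devmap).pct["abn1"] == pytest.approx(7.0)

    def test_inner_oval_excluded_from_annulus(self):
        geom = geom_n(100)
        devmap = wnl_map(geom)
        ann = AnnulusSpec(center_px=geom.fovea_px)
        inner = ann._quad(geom, ann.inner_semiaxes_mm) <= 1.0
        devmap.categories[inner] = int(DeviationCategory.ABNORMAL_1)
        summ = extent_summary(devmap, ann)
        # membership by pixel centers: the inner oval is outside the annulus
        assert summ.pct["abn1"] == 0.0

    def test_conservation(self, models64, rng):
        from macudev import classify_thickness

        thickness = rng.normal(models64["gcl"].mean_surface, 4.0)
        devmap = classify_thickness(models64["gcl"], np.clip(thickness, 0, None))
        counts = devmap.counts()
        assert sum(counts.values()) == devmap.categories.size
        summ = extent_summary(devmap, denominator="raw")
        assert sum(summ.pct.values()) <= 100.0
        wnl_pct = 100.0 * counts[DeviationCategory.WNL] / summ.n_total_px
        exc_pct = 100.0 * summ.n_excluded_px / summ.n_total_px
        assert sum(summ.pct.values()) + wnl_pct + exc_pct == pytest.approx(100.0)

    def test_denominator_policy_differs_only_with_excluded(self, geom64):
        devmap = wnl_map(geom64)
        devmap.categories.ravel()[:50] = int(DeviationCategory.ABNORMAL_1)
        a = extent_summary(devmap, denominator="exclude")
        b = extent_summary(devmap, denominator="raw")
        assert a.pct == b.pct  # no EXCLUDED pixels -> identical
        devmap.categories.ravel()[50:150] = int(DeviationCategory.EXCLUDED)
        a = extent_summary(devmap, denominator="exclude")
        b = extent_summary(devmap, denominator="raw")
        assert a.pct["abn1"] > b.pct["abn1"]
        assert b.n_total_px - a.n_total_px == 100

    def test_cumulative_reporting(self, geom64):
        devmap = wnl_map(geom64)
        devmap.categories.ravel()[:10] = int(DeviationCategory.ABNORMAL_1)
        devmap.categories.ravel()[10:30] = int(DeviationCategory.BORDERLINE_5)
        disjoint = extent_summary(devmap)
        cumulative = extent_summary(devmap, cumulative=True)
        assert cumulative.pct["abn5"] == pytest.approx(
            disjoint.pct["abn1"] + disjoint.pct["abn5"]
        )
        assert cumulative.pct["abn1"] == disjoint.pct["abn1"]

    def test_annulus_area_matches_analytic_within_2pct(self):
        geom = geom_n(384)
        ann = AnnulusSpec(center_px=geom.fovea_px)
        n_px = int(ann.membership(geom).sum())
        analytic = ann.area_mm2() / (geom.pitch_mm[0] * geom.pitch_mm[1])
        assert abs(n_px - analytic) / analytic < 0.02

    def test_pipeline_equivalence_direct_vs_rendered(self, models64, geom64, rng):
        """Extents from the raster equal extents from render -> parse."""
        from macudev import classify_thickness

        thickness = rng.normal(models64["gcl"].mean_surface, 3.0)
        devmap = classify_thickness(models64["gcl"], np.clip(thickness, 0, None))
        img = render_deviation_map(devmap)  # no overlay graphics
        parsed = parse_colors(img, geometry=geom64)
        assert extent_summary(parsed).pct == extent_summary(devmap).pct
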