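"""Band masks and the DT/MT and SAR/AFR intensity ratios."""

import numpy as np
import pytest

from tracheoquant.errors import GeometryError, MeasurementError
from tracheoquant.image import MultiChannelImage, PolygonROI, PolylineROI
from tracheoquant.intensity import band_pixels, dt_mt_ratio, sar_afr_ratio
from tracheoquant.phantoms import ApicalCellParams, generate_apical_cell


def brute_force_band(pts, width, shape):
    """Literal per-pixel oracle: perpendicular strip of each segment plus
    discs at interior vertices."""
    pts = np.asarray(pts, float)
    h, w = shape
    half = width / 2.0
    mask = np.zeros(shape, dtype=bool)
    for y in range(h):
        for x in range(w):
            best = np.inf
            for p0, p1 in zip(pts[:-1], pts[1:]):
                d = p1 - p0
                len2 = d @ d
                t = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / len2
                if 0 <= t <= 1:
                    proj = p0 + t * d
                    best = min(best, np.hypot(x - proj[0], y - proj[1]))
            for j in pts[1:-1]:
                best = min(best, np.hypot(x - j[0], y - j[1]))
            mask[y, x] = best <= half
    return mask


class TestBandPixels:
    def test_horizontal_line_width_one_is_ten_pixels(self):
        line = PolylineROI([(0.0, 5.0), (9.0, 5.0)])
        assert band_pixels(line, 1, (11, 11)).sum() == 10

    def test_width_three_is_thirty_pixels(self):
        line = PolylineROI([(0.0, 5.0), (9.0, 5.0)])
        mask = band_pixels(line, 3, (11, 11))
        assert mask.sum() == 30
        assert np.array_equal(mask, brute_force_band(line.points, 3, (11, 11)))

    def test_bent_polyline_matches_bruteforce_oracle(self):
        pts = [(2.0, 2.0), (10.0, 3.0), (13.0, 12.0)]
        mask = band_pixels(PolylineROI(pts), 5, (16, 16))
        assert np.array_equal(mask, brute_force_band(pts, 5, (16, 16)))

    def test_clipped_band_matches_in_bounds_oracle(self):
        pts = [(1.0, 1.0), (14.0, 1.0)]
        with pytest.warns(UserWarning, match="clipped"):
            mask = band_pixels(PolylineROI(pts), 9, (8, 16))
        oracle = brute_force_band(pts, 9, (8, 16))
        assert np.array_equal(mask, oracle)


class TestDtMtRatio:
    def _image(self, plane):
        return MultiChannelImage(np.asarray(plane, float)[None], ["crb"], 0.1)

    def test_uniform_image_ratio_one(self):
        img = self._image(np.full((60, 120), 37.0))
        dt = PolylineROI([(20.0, 20.0), (100.0, 20.0)], width_px=10)
        mt = PolylineROI([(20.0, 45.0), (100.0, 45.0)], width_px=6)
        assert dt_mt_ratio(img, 0, dt, mt).ratio == pytest.approx(1.0)

    def test_painted_bands_ratio_two(self):
        plane = np.zeros((120, 200))
        plane[30:50, 10:190] = 200.0
        plane[80:90, 10:190] = 100.0
        img = self._image(plane)
        dt = PolylineROI([(20.0, 39.5), (180.0, 39.5)], width_px=20)
        mt = PolylineROI([(20.0, 84.5), (180.0, 84.5)], width_px=10)
        res = dt_mt_ratio(img, 0, dt, mt)
        assert res.dt_mean == pytest.approx(200.0)
        assert res.mt_mean == pytest.approx(100.0)
        assert res.ratio == pytest.approx(2.0)

    def test_poisson_replicates_recover_planted_ratio(self):
        # planted ratio 1.5 under shot noise; 10 replicates within 5%
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            plane = np.full((150, 260), 2.0)
            plane[40:100, 20:240] = 150.0
            plane[120:130, 20:240] = 100.0
            img = self._image(rng.poisson(plane))
            dt = PolylineROI([(25.0, 69.5), (234.0, 69.5)], width_px=60)
            mt = PolylineROI([(25.0, 124.5), (234.0, 124.5)], width_px=10)
            ratios.append(dt_mt_ratio(img, 0, dt, mt).ratio)
        assert np.mean(ratios) == pytest.approx(1.5, rel=0.05)

    def test_zero_reference_rejected(self):
        plane = np.zeros((60, 120))
        plane[10:20, :] = 50.0
        img = self._image(plane)
        dt = PolylineROI([(20.0, 14.5), (100.0, 14.5)], width_px=10)
        mt = PolylineROI([(20.0, 45.0), (100.0, 45.0)], width_px=6)
        with pytest.raises(MeasurementError):
            dt_mt_ratio(img, 0, dt, mt)

    def test_illumination_invariance_and_monotonicity(self):
        plane = np.zeros((120, 200))
        plane[30:50, 10:190] = 120.0
        plane[80:90, 10:190] = 100.0
        dt = PolylineROI([(20.0, 39.5), (180.0, 39.5)], width_px=20)
        mt = PolylineROI([(20.0, 84.5), (180.0, 84.5)], width_px=10)
        base = dt_mt_ratio(self._image(plane), 0, dt, mt).ratio
        scaled = dt_mt_ratio(self._image(plane * 7.3), 0, dt, mt).ratio
        assert scaled == pytest.approx(base, rel=1e-12)
        brighter = plane.copy()
        brighter[30:50, 10:190] = 150.0
        assert dt_mt_ratio(self._image(brighter), 0, dt, mt).ratio > base


class TestSarAfrRatio:
    POLY = ((10.0, 10.0), (60.0, 10.0), (60.0, 60.0), (10.0, 60.0))
    INNER = ((13.0, 13.0), (57.0, 13.0), (57.0, 57.0), (13.0, 57.0))

    def _phantom(self, clean_imaging, sar=200.0, afr=100.0):
        img, truth = generate_apical_cell(
            ApicalCellParams(
                contour_polygon=self.POLY, sar_band_width_um=0.3,
                sar_intensity=sar, afr_intensity=afr,
            ),
            clean_imaging,
        )
        return img, truth

    def test_recovers_generating_ratio_noiseless(self, clean_imaging):
        img, truth = self._phantom(clean_imaging)
        res = sar_afr_ratio(
            img, 0, PolygonROI(np.array(self.POLY)), PolygonROI(np.array(self.INNER)),
            band_width_px=5,
        )
        assert res.ratio == pytest.approx(truth.sar_afr_true_ratio, rel=0.03)

    @pytest.mark.parametrize("planted", [0.5, 1.0, 2.0, 4.0])
    def test_recovery_across_planted_ratios(self, clean_imaging, planted):
        img, truth = self._phantom(clean_imaging, sar=100.0 * planted, afr=100.0)
        res = sar_afr_ratio(
            img, 0, PolygonROI(np.array(self.POLY)), PolygonROI(np.array(self.INNER)),
            band_width_px=5,
        )
        assert res.ratio == pytest.approx(truth.sar_afr_true_ratio, rel=0.05)

    def test_equal_band_and_interior_signal_gives_ratio_one(self, clean_imaging):
        img, truth = self._phantom(clean_imaging)
        # scale intensities so planted band and interior total intensities match
        res = sar_afr_ratio(
            img, 0, PolygonROI(np.array(self.POLY)), PolygonROI(np.array(self.INNER)),
            band_width_px=5,
        )
        assert res.ratio / truth.sar_afr_true_ratio == pytest.approx(1.0, rel=0.03)

    def test_illumination_invariance(self, clean_imaging):
        img, _ = self._phantom(clean_imaging)
        contour = PolygonROI(np.array(self.POLY))
        inner = PolygonROI(np.array(self.INNER))
        base = sar_afr_ratio(img, 0, contour, inner, 5).ratio
        scaled_img = MultiChannelImage(img.pixels * 3.5, ["apical"], img.pixel_size_um)
        assert sar_afr_ratio(scaled_img, 0, contour, inner, 5).ratio == pytest.approx(
            base, rel=1e-12
        )

    def test_inner_touching_contour_raises(self, clean_imaging):
        img, _ = self._phantom(clean_imaging)
        touching = PolygonROI(
            np.array([(11.0, 11.0), (59.0, 11.0), (59.0, 59.0), (11.0, 59.0)])
        )
        with pytest.raises(GeometryError):
            sar_afr_ratio(img, 0, PolygonROI(np.array(self.POLY)), touching, 5)
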