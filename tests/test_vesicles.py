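"""Vesicle detection, diameters, cargo classes, census, nuclei counting."""

import numpy as np
import pytest

from tracheoquant.errors import MeasurementError
from tracheoquant.image import MultiChannelImage
from tracheoquant.phantoms import (
    ImagingParams,
    NucleiFieldParams,
    VesicleFieldParams,
    generate_nuclei_field,
    generate_vesicle_field,
)
from tracheoquant.vesicles import (
    VesicleDetection,
    census,
    classify_cargo,
    count_nuclei,
    detect_vesicles,
    equivalent_diameter_um,
    psf_corrected_diameter_um,
)


class TestDetection:
    def test_recall_and_precision_on_default_phantom(self, default_imaging):
        p = VesicleFieldParams(n_vesicles=50)
        img, truth = generate_vesicle_field(p, default_imaging)
        dets = detect_vesicles(img, min_diameter_um=0.3, max_diameter_um=0.9)
        planted = np.array([v["centroid"] for v in truth.vesicles])
        found = np.array([d.centroid for d in dets])
        # match detections to planted positions within 2 px
        dist = np.hypot(
            planted[:, None, 0] - found[None, :, 0],
            planted[:, None, 1] - found[None, :, 1],
        )
        matched_planted = (dist.min(axis=1) <= 2.0).sum()
        matched_found = (dist.min(axis=0) <= 2.0).sum()
        assert matched_planted >= 48  # recall >= 96%
        assert matched_found == len(dets)  # no spurious detections

    def test_blank_image_gives_empty_list(self):
        img = MultiChannelImage(np.zeros((2, 64, 64)), ["ch1", "ch2"], 0.1)
        assert detect_vesicles(img) == []

    def test_two_vesicles_at_min_separation_resolved(self, default_imaging):
        p = VesicleFieldParams(n_vesicles=2, min_separation_um=1.2, fov_um=(8.0, 8.0))
        img, truth = generate_vesicle_field(p, default_imaging)
        dets = detect_vesicles(img, min_diameter_um=0.3, max_diameter_um=0.9)
        assert len(dets) == 2


class TestDiameter:
    def test_perfect_disc_radius_five_px(self):
        # area of the rasterized disc approximates pi * r^2
        yy, xx = np.mgrid[0:21, 0:21]
        area = int(((xx - 10) ** 2 + (yy - 10) ** 2 <= 25).sum())
        assert equivalent_diameter_um(area, 0.1) == pytest.approx(1.0, rel=0.02)

    def test_empty_region_rejected(self):
        with pytest.raises(MeasurementError):
            equivalent_diameter_um(0, 0.1)

    def test_psf_correction_is_identity_without_psf(self):
        assert psf_corrected_diameter_um(0.8, 0.0) == 0.8

    def test_large_planted_diameter_recovered_within_ten_percent(self):
        imaging = ImagingParams(seed=3)
        p = VesicleFieldParams(
            n_vesicles=20, p_both=0.0, p_ch1_only=1.0, p_ch2_only=0.0,
            diameter_um_mean=1.3, diameter_um_sd=0.0, min_separation_um=3.9,
        )
        img, _ = generate_vesicle_field(p, imaging)
        dets = detect_vesicles(
            img, channels=["ch1"], min_diameter_um=0.4, max_diameter_um=3.9,
            psf_sigma_um=imaging.psf_sigma_um,
        )
        assert len(dets) >= 18
        assert np.mean([d.diameter_um for d in dets]) == pytest.approx(1.3, rel=0.10)

    def test_near_resolution_diameter_recovered_within_twenty_percent(self):
        imaging = ImagingParams(
            pixel_size_um=0.05, psf_sigma_um=0.1, poisson_noise=False,
            read_noise_sigma=0.0, seed=4,
        )
        p = VesicleFieldParams(
            n_vesicles=20, p_both=0.0, p_ch1_only=1.0, p_ch2_only=0.0,
            diameter_um_mean=0.28, diameter_um_sd=0.0, min_separation_um=1.0,
        )
        img, _ = generate_vesicle_field(p, imaging)
        dets = detect_vesicles(
            img, channels=["ch1"], min_diameter_um=0.1, max_diameter_um=0.9,
            psf_sigma_um=imaging.psf_sigma_um,
        )
        assert len(dets) >= 18
        assert np.mean([d.diameter_um for d in dets]) == pytest.approx(0.28, rel=0.20)


class TestCargoClassification:
    def _classified_detections(self, imaging, **kw):
        p = VesicleFieldParams(**kw)
        img, truth = generate_vesicle_field(p, imaging)
        dets = detect_vesicles(img, min_diameter_um=0.3, max_diameter_um=0.9)
        for d in dets:
            classify_cargo(d, img, "ch1", "ch2")
        return img, truth, dets

    def test_dual_and_single_cargo_fields_classified(self, default_imaging):
        _, _, dets = self._classified_detections(
            default_imaging, n_vesicles=12, p_both=1.0, p_ch1_only=0.0, p_ch2_only=0.0
        )
        assert dets and all(d.cargo_class == "both" for d in dets)
        _, _, dets = self._classified_detections(
            default_imaging, n_vesicles=12, p_both=0.0, p_ch1_only=1.0, p_ch2_only=0.0
        )
        assert dets and all(d.cargo_class == "ch1_only" for d in dets)

    def test_classification_invariant_under_common_rescaling(self, default_imaging):
        p = VesicleFieldParams(n_vesicles=20)
        img, _ = generate_vesicle_field(p, default_imaging)
        dets = detect_vesicles(img, min_diameter_um=0.3, max_diameter_um=0.9)
        classes = [classify_cargo(d, img, "ch1", "ch2") for d in dets]
        scaled = MultiChannelImage(img.pixels * 3.7, img.channel_names, img.pixel_size_um)
        rescaled_classes = [classify_cargo(d, scaled, "ch1", "ch2") for d in dets]
        assert classes == rescaled_classes

    def test_census_recovery_at_n194(self):
        imaging = ImagingParams(seed=0)
        img, truth = generate_vesicle_field(
            VesicleFieldParams(n_vesicles=194, p_both=0.67, p_ch1_only=0.15, p_ch2_only=0.18),
            imaging,
        )
        dets = detect_vesicles(img, min_diameter_um=0.3, max_diameter_um=0.9)
        for d in dets:
            classify_cargo(d, img, "ch1", "ch2")
        measured = census(dets)
        planted = {
            c: sum(v["cargo_class"] == c for v in truth.vesicles)
            for c in ("both", "ch1_only", "ch2_only")
        }
        n = len(truth.vesicles)
        for cls in planted:
            p_hat = planted[cls] / n
            se = np.sqrt(p_hat * (1 - p_hat) / n)
            assert abs(measured.proportions[cls] - p_hat) <= 3 * se


class TestCensus:
    def _det(self, cls):
        d = VesicleDetection(centroid=(0, 0), diameter_um=0.5, mask=np.ones((1, 1), bool))
        d.cargo_class = cls
        return d

    def test_simple_tally(self):
        dets = [self._det("both")] * 10 + [self._det("ch1_only")] * 5 + [self._det("ch2_only")] * 5
        res = census(dets)
        assert res.proportions == {"both": 0.5, "ch1_only": 0.25, "ch2_only": 0.25}

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(9)
        classes = rng.choice(["both", "ch1_only", "ch2_only", None], size=60).tolist()
        res = census([self._det(c) for c in classes])
        kept = [c for c in classes if c]
        assert res.n_total == len(kept)
        assert res.n_both == kept.count("both")
        assert res.n_ch1_only == kept.count("ch1_only")
        assert res.n_ch2_only == kept.count("ch2_only")
        if res.n_total:
            assert sum(res.proportions.values()) == pytest.approx(1.0)

    def test_empty_census_flagged_undefined(self):
        res = census([])
        assert res.n_total == 0
        assert all(np.isnan(v) for v in res.proportions.values())


class TestCountNuclei:
    def test_planted_twenty_six_counted_exactly(self, default_imaging):
        img, _ = generate_nuclei_field(NucleiFieldParams(n_nuclei=26), default_imaging)
        assert count_nuclei(img, "nuclei") == 26

    def test_blank_image_counts_zero(self):
        img = MultiChannelImage(np.zeros((1, 64, 64)), ["nuclei"], 0.1)
        assert count_nuclei(img, 0) == 0

    def test_exact_recovery_rate_over_100_phantoms(self):
        # planted counts 20..30; exact recovery in >= 95/100 fields
        rng = np.random.default_rng(12)
        exact = 0
        for i in range(100):
            n = int(rng.integers(20, 31))
            img, _ = generate_nuclei_field(
                NucleiFieldParams(n_nuclei=n), ImagingParams(seed=1000 + i)
            )
            exact += count_nuclei(img, "nuclei") == n
        assert exact >= 95
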