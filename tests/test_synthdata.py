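import dataclasses
import math

import numpy as np
import pytest
from scipy.special import i0, i1

from helpers import oracle_hue_bin
from myoaniso import (
    HistologyComposition,
    OrientationModel,
    PhantomParams,
    TreatmentProtocol,
    aniso_scale_at,
    generate_histology_image,
    generate_phantom_frame,
    generate_treatment_series,
    sample_orientations,
)
from myoaniso.echoroi import CardinalROI, extract_roi_mean, mid_myocardial_points
from myoaniso.geometry import Ellipse, GeometryError, WallGeometry
from myoaniso.psrhist import analyze_slide, hue_bins
from myoaniso.synthdata import HISTOLOGY_CLASS_CODES, expected_intensity_field, rgb_for_hue_bin


class TestPhantomFrame:
    def test_noiseless_two_level_dichotomy(self, small_params):
        # integer-centred annulus so pixels lie exactly on the beam axis
        geometry = WallGeometry(
            endo=Ellipse(80, 80, 33, 33), epi=Ellipse(80, 80, 66, 66)
        )
        frame = generate_phantom_frame(geometry, small_params, aniso_scale=1.0)
        pts = mid_myocardial_points(geometry)
        # on the beam axis the cos^2 interpolation is exactly at its extremes
        assert frame.pixels[int(pts["anterior"][0]), 80] == pytest.approx(40.0)
        assert frame.pixels[int(pts["posterior"][0]), 80] == pytest.approx(40.0)
        assert frame.pixels[80, int(pts["lateral"][1])] == pytest.approx(10.0)
        # ROI means are within the cos^2 curvature of the extreme levels
        ant = extract_roi_mean(frame, CardinalROI("anterior", pts["anterior"]))
        lat = extract_roi_mean(frame, CardinalROI("lateral", pts["lateral"]))
        assert ant == pytest.approx(40.0, rel=5e-3)
        assert lat == pytest.approx(10.0, rel=1.5e-2)

    def test_background_levels(self, small_params, small_geometry):
        frame = generate_phantom_frame(small_geometry, small_params, aniso_scale=1.0)
        assert frame.pixels[0, 0] == pytest.approx(small_params.background)
        cr, cc = (int(v) for v in small_geometry.epi.center)
        assert frame.pixels[cr, cc] == pytest.approx(small_params.background)  # chamber

    def test_isotropic_phantom_flat_annulus(self, small_params, small_geometry):
        field = expected_intensity_field(small_geometry, small_params, aniso_scale=0.0)
        rows, cols = np.mgrid[0:160, 0:160]
        annulus = small_geometry.epi.contains(rows, cols) & ~small_geometry.endo.contains(
            rows, cols
        )
        assert np.allclose(field[annulus], small_params.intensity_perp)

    def test_speckled_roi_mean_within_4_se(self, small_geometry):
        params = PhantomParams(
            speckle_model="exponential", image_size_px=(160, 160), pixel_size_um=25.0, seed=3
        )
        frame = generate_phantom_frame(small_geometry, params, aniso_scale=1.0)
        pts = mid_myocardial_points(small_geometry)
        mean = extract_roi_mean(frame, CardinalROI("anterior", pts["anterior"]))
        se = 40.0 / math.sqrt(100)  # exponential speckle: SD = mean
        assert abs(mean - 40.0) < 4 * se

    def test_speckle_means_unbiased(self, small_geometry):
        """Unit-mean speckle: ROI sample means are unbiased over >=200 draws."""
        pts = mid_myocardial_points(small_geometry)
        roi = CardinalROI("anterior", pts["anterior"])
        means = []
        for seed in range(200):
            params = PhantomParams(
                speckle_model="exponential",
                image_size_px=(160, 160),
                pixel_size_um=25.0,
                seed=seed,
            )
            frame = generate_phantom_frame(small_geometry, params, aniso_scale=1.0)
            means.append(extract_roi_mean(frame, roi))
        noiseless = generate_phantom_frame(
            small_geometry, dataclasses.replace(params, speckle_model="none"), aniso_scale=1.0
        )
        expected = extract_roi_mean(noiseless, roi)
        se = expected / math.sqrt(100 * 200)
        assert abs(np.mean(means) - expected) < 4 * se

    def test_fixed_seed_bit_identical(self, small_geometry, small_speckled_params):
        f1 = generate_phantom_frame(small_geometry, small_speckled_params)
        f2 = generate_phantom_frame(small_geometry, small_speckled_params)
        assert np.array_equal(f1.pixels, f2.pixels)

    def test_rotation_invariant_mean_annulus_intensity(self, small_params):
        """cos^2 integrates identically however the ellipse pair is rotated."""
        means = []
        for rot in (0.0, 30.0, 75.0):
            geom = WallGeometry(
                endo=Ellipse(79.5, 79.5, 40, 55, rot),
                epi=Ellipse(79.5, 79.5, 60, 70, rot),
            )
            field = expected_intensity_field(geom, small_params, aniso_scale=1.0)
            rows, cols = np.mgrid[0:160, 0:160]
            annulus = geom.epi.contains(rows, cols) & ~geom.endo.contains(rows, cols)
            means.append(field[annulus].mean())
        # pixelation of the annulus mask limits the match, not the cos^2 law
        assert np.allclose(means, means[0], rtol=2e-2)

    def test_annulus_outside_image_raises(self, small_params):
        geom = WallGeometry(
            endo=Ellipse(80, 80, 40, 40),
            epi=Ellipse(80, 80, 100, 100),
        )
        with pytest.raises(GeometryError):
            generate_phantom_frame(geom, small_params)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(intensity_perp=5.0, intensity_par=10.0)


class TestTreatmentSeries:
    def test_control_13_frames_constant(self, small_params, small_geometry):
        proto = TreatmentProtocol(arm="control")
        frames = generate_treatment_series(small_geometry, small_params, proto)
        assert len(frames) == 13
        assert all(aniso_scale_at(proto, t) == 1.0 for t in proto.timepoints_min)
        # noiseless control frames are identical at all timepoints
        assert all(np.array_equal(f.pixels, frames[0].pixels) for f in frames)

    def test_collagenase10_decay_freezes(self):
        proto = TreatmentProtocol(arm="collagenase10", decay_rate_per_min=0.1)
        assert aniso_scale_at(proto, 10.0) == pytest.approx(math.exp(-1.0))
        assert aniso_scale_at(proto, 25.0) == pytest.approx(math.exp(-1.0))

    def test_infinite_rate_limit_is_isotropic(self):
        proto = TreatmentProtocol(arm="collagenase30", decay_rate_per_min=1e9)
        assert aniso_scale_at(proto, 0.0) == 1.0
        for t in (2.5, 10.0, 30.0):
            assert aniso_scale_at(proto, t) == pytest.approx(0.0, abs=1e-300)

    def test_gap_monotone_nonincreasing(self, small_params, small_geometry):
        proto = TreatmentProtocol(arm="collagenase30", decay_rate_per_min=0.1)
        frames = generate_treatment_series(small_geometry, small_params, proto)
        pts = mid_myocardial_points(small_geometry)
        gaps = [
            extract_roi_mean(f, CardinalROI("anterior", pts["anterior"]))
            - extract_roi_mean(f, CardinalROI("lateral", pts["lateral"]))
            for f in frames
        ]
        assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            TreatmentProtocol(arm="control", interval_min=0)
        with pytest.raises(ValueError):
            TreatmentProtocol(arm="collagenase30", collagenase_stop_min=40.0)


class TestHistologyImage:
    def test_exact_pixel_allocation(self):
        comp = HistologyComposition(
            fraction_red_orange=0.25,
            fraction_yellow=0.0,
            fraction_green=0.0,
            fraction_background=0.75,
            hue_per_class={"red_orange": 20, "yellow": 45, "green": 60},
            image_size_px=(100, 100),
            seed=0,
        )
        _, mask = generate_histology_image(comp)
        assert (mask == HISTOLOGY_CLASS_CODES["red_orange"]).sum() == 2500

    def test_pure_green_hue_recovered(self):
        comp = HistologyComposition(
            fraction_red_orange=0.0,
            fraction_yellow=0.0,
            fraction_green=1.0,
            fraction_background=0.0,
            hue_per_class={"red_orange": 20, "yellow": 45, "green": 90},
            image_size_px=(20, 20),
            seed=0,
        )
        rgb, _ = generate_histology_image(comp)
        assert np.all(hue_bins(rgb) == 90)
        # independent colorsys check on one pixel
        assert oracle_hue_bin(*(int(v) for v in rgb[0, 0])) == 90

    def test_roundtrip_collagen_content(self):
        comp = HistologyComposition(
            fraction_red_orange=0.1,
            fraction_yellow=0.1,
            fraction_green=0.1,
            fraction_background=0.7,
            hue_per_class={"red_orange": 10, "yellow": 45, "green": 60},
            image_size_px=(100, 100),
            seed=1,
        )
        rgb, _ = generate_histology_image(comp)
        cls = analyze_slide(rgb)
        assert cls.collagen_content_pct == pytest.approx(30.0, abs=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            HistologyComposition(
                fraction_red_orange=0.5,
                fraction_yellow=0.0,
                fraction_green=0.0,
                fraction_background=0.4,
            )

    def test_hue_outside_class_range_rejected(self):
        with pytest.raises(ValueError):
            HistologyComposition(hue_per_class={"red_orange": 40, "yellow": 45, "green": 60})

    @pytest.mark.parametrize("hue_bin", [2, 20, 38, 42, 43, 51, 60, 85, 90, 128])
    def test_rgb_for_hue_bin_exact(self, hue_bin):
        rgb = rgb_for_hue_bin(hue_bin)
        assert oracle_hue_bin(*rgb) == hue_bin


class TestOrientationSampling:
    def test_concentration_limit(self):
        model = OrientationModel(mean_angle_deg=30.0, kappa=1e9, n=50, seed=0)
        sample = sample_orientations(model)
        assert np.all(np.abs(sample.angles_deg - 30.0) < 0.1)
        assert sample.n == 50
        assert sample.grid.shape == (50, 2)

    def test_uniform_limit_resultant_vanishes(self):
        model = OrientationModel(mean_angle_deg=30.0, kappa=0.0, n=100_000, seed=1)
        sample = sample_orientations(model)
        doubled = np.radians(2 * sample.angles_deg)
        r = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
        assert r < 0.02

    def test_kappa2_resultant_matches_bessel_ratio(self):
        model = OrientationModel(mean_angle_deg=30.0, kappa=2.0, n=100_000, seed=2)
        sample = sample_orientations(model)
        doubled = np.radians(2 * sample.angles_deg)
        r = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
        assert abs(r - i1(2.0) / i0(2.0)) < 0.01

    def test_angles_in_support_and_reproducible(self):
        model = OrientationModel(mean_angle_deg=170.0, kappa=1.0, n=500, seed=7)
        s1 = sample_orientations(model)
        s2 = sample_orientations(model)
        assert np.array_equal(s1.angles_deg, s2.angles_deg)
        assert np.all((s1.angles_deg >= 0) & (s1.angles_deg < 180))
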