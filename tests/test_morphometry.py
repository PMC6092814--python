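"""Nucleus segmentation, ellipse morphometry and radial profiles."""

import math

import numpy as np
import pandas as pd
import pytest

import swirlwell as sw
from conftest import match_detections
from oracles import rasterize_ellipse


class TestMaxProjection:
    def test_single_slice_is_identity(self):
        img = np.arange(12, dtype=np.uint16).reshape(3, 4)
        frame = sw.ImageFrame(img[None, :, :], 0.65)
        proj = sw.max_projection(frame)
        assert np.array_equal(proj.pixels, img)

    def test_disjoint_spots_union(self):
        a = np.zeros((8, 8), dtype=np.uint16)
        b = np.zeros((8, 8), dtype=np.uint16)
        a[1, 1] = 100
        b[6, 6] = 80
        proj = sw.max_projection(sw.ImageFrame(np.stack([a, b]), 1.0))
        assert proj.pixels[1, 1] == 100 and proj.pixels[6, 6] == 80

    def test_mismatched_slices_rejected(self):
        with pytest.raises(ValueError):
            sw.ImageFrame(np.empty((2,)), 1.0)


class TestFitEllipse:
    def test_rasterized_circle_is_round(self):
        mask = rasterize_ellipse(20, 20, 0.0)
        fit = sw.fit_ellipse(mask)
        assert fit.semi_major_px / fit.semi_minor_px == pytest.approx(1.0, abs=0.02)
        assert fit.semi_major_px == pytest.approx(20, rel=0.02)

    @pytest.mark.parametrize("angle", [30.0, -60.0, 0.0, 90.0])
    def test_rasterized_ellipse_axes_and_angle(self, angle):
        mask = rasterize_ellipse(24, 12, angle)
        fit = sw.fit_ellipse(mask)
        assert fit.semi_major_px / fit.semi_minor_px == pytest.approx(2.0, rel=0.02)
        diff = abs(sw.wrap_axial_deg(fit.angle_deg - angle))
        assert diff <= 2.0

    def test_tiny_region_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1:5] = True  # 4 pixels
        with pytest.raises(ValueError, match="5"):
            sw.fit_ellipse(mask)

    def test_si_scale_invariant(self):
        # rasterize the same 2:1 ellipse at three scales
        sis = []
        for a in (12, 24, 48):
            mask = rasterize_ellipse(a, a / 2, 20.0)
            fit = sw.fit_ellipse(mask)
            area = math.pi * fit.semi_major_px * fit.semi_minor_px
            per = sw.ellipse_perimeter(fit.semi_major_px, fit.semi_minor_px)
            sis.append(sw.shape_index(area, per))
        assert np.ptp(sis) < 0.02


class TestShapeIndex:
    def test_circle_gives_exactly_one(self):
        for r in (0.3, 1.0, 17.4):
            assert sw.shape_index(math.pi * r**2, 2 * math.pi * r) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_two_to_one_ellipse(self):
        # perimeter from the elliptic-integral oracle: P(2,1) ~ 9.6884
        p = sw.ellipse_perimeter(2.0, 1.0)
        assert p == pytest.approx(9.6884, abs=2e-4)
        assert sw.shape_index(math.pi * 2.0, p) == pytest.approx(0.8412, abs=5e-4)

    def test_tends_to_zero_for_degenerate_ellipses(self):
        ratios = [1, 2, 5, 20, 100]
        sis = [
            sw.shape_index(math.pi * e, sw.ellipse_perimeter(e, 1.0)) for e in ratios
        ]
        assert all(np.diff(sis) < 0)
        assert sis[-1] < 0.06

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sw.shape_index(0.0, 1.0)
        with pytest.raises(ValueError):
            sw.shape_index(1.0, -1.0)

    def test_overshoot_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            si = sw.shape_index(1.01 * math.pi, 2 * math.pi)
        assert si == 1.0


class TestRadialOrientation:
    CENTRE = (0.0, 100.0)  # well centre left of the nucleus, same row

    def test_radially_aligned_is_zero(self):
        # radial direction is +x; axis along x
        assert sw.radial_orientation((50.0, 100.0), 0.0, self.CENTRE) == pytest.approx(0.0)

    def test_perpendicular_reports_plus_ninety(self):
        val = sw.radial_orientation((50.0, 100.0), 90.0, self.CENTRE)
        assert val == pytest.approx(90.0)

    def test_inner_end_right_of_reference_is_positive(self):
        # reference vector points +x (outward); rotate the long axis +30 deg
        # CCW (physical frame): the inner end then sits 30 deg to the right
        # of the outward reference seen from the centre
        val = sw.radial_orientation((50.0, 100.0), 30.0, self.CENTRE)
        assert val == pytest.approx(30.0)
        val = sw.radial_orientation((50.0, 100.0), -30.0, self.CENTRE)
        assert val == pytest.approx(-30.0)

    def test_sign_convention_constructed_nucleus(self):
        # nucleus north of the centre: reference vector +y (physical).
        # A long axis at 120 deg points up-left, so the inner end (pointing
        # down-right, toward the centre) is displaced to the right of the
        # reference -> +30
        centre = (100.0, 100.0)
        val = sw.radial_orientation((100.0, 40.0), 120.0, centre)
        assert val == pytest.approx(30.0)

    def test_centroid_at_centre_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            sw.radial_orientation((10.0, 10.0), 45.0, (10.0, 10.0))

    def test_invariant_under_image_rotation(self):
        # rotating the whole image about the well centre rotates the radial
        # reference with it, leaving signed orientations unchanged
        spec = sw.SyntheticWellSpec(seed=11, kappa_centre=3.0, kappa_edge=3.0,
                                    axis_ratio_centre=2.0, axis_ratio_edge=2.0)
        frame, truth, meta = sw.generate_well_image(spec, kind="disc",
                                                    disc_radius_mm=0.4)
        det = sw.segment_nuclei(frame)
        n = frame.pixels.shape[0]
        rot_frame = sw.ImageFrame(np.rot90(frame.pixels).copy(), frame.pixel_size_um,
                                  frame.well_centre_px)
        det_rot = sw.segment_nuclei(rot_frame)
        # map original centroids through the rotation: (x, y) -> (y, n-1-x)
        mapped = det.copy()
        mapped["x_px"], mapped["y_px"] = det["y_px"], n - 1 - det["x_px"]
        n_match, idx, _ = match_detections(mapped, det_rot, tol_px=2.0)
        assert n_match == len(det)
        diff = sw.wrap_axial_deg(
            det_rot["orientation_deg"].to_numpy()[idx]
            - mapped["orientation_deg"].to_numpy()
        )
        assert np.max(np.abs(diff)) < 2.0


class TestSegmentation:
    def test_counts_exactly_on_clean_synthetic_image(self):
        spec = sw.SyntheticWellSpec(seed=21, density_centre_per_mm2=250,
                                    density_edge_per_mm2=250)
        frame, truth, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.55)
        det = sw.segment_nuclei(frame)
        assert len(det) == len(truth)
        n_match, _, _ = match_detections(truth, det)
        assert n_match == len(truth)

    def test_blank_image_gives_zero_detections(self):
        frame = sw.ImageFrame(np.full((128, 128), 100, dtype=np.uint16), 0.65)
        with pytest.warns(UserWarning):
            det = sw.segment_nuclei(frame)
        assert len(det) == 0

    def test_area_filter_excludes_small_nuclei(self):
        spec = sw.SyntheticWellSpec(seed=3)
        frame, truth, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.3)
        assert len(truth) > 0
        det = sw.segment_nuclei(frame, area_range_um2=(truth.area_um2.max() * 2, 1e5))
        assert len(det) == 0

    def test_stack_input_rejected(self):
        frame = sw.ImageFrame(np.zeros((2, 16, 16), dtype=np.uint16), 1.0)
        with pytest.raises(ValueError, match="max_projection"):
            sw.segment_nuclei(frame)


class TestBinByRadius:
    def _records(self, r_values, si=0.9, orient=10.0):
        n = len(r_values)
        return pd.DataFrame(
            {
                "x_px": np.zeros(n), "y_px": np.zeros(n), "r_mm": r_values,
                "si": np.full(n, si), "orientation_deg": np.full(n, orient),
            }
        )

    def test_point_mass_occupies_single_bin(self):
        prof = sw.bin_by_radius(self._records([5.5] * 7), 1.0, 1.0, 10.0)
        assert prof["count"].tolist() == [0, 0, 0, 0, 0, 7, 0, 0, 0, 0]

    def test_uniform_density_recovered(self):
        rng = np.random.default_rng(0)
        # uniform density on a strip: r uniform, area per bin equal
        r = rng.uniform(0, 10, 4000)
        prof = sw.bin_by_radius(self._records(r), bin_area_mm2=2.0,
                                bin_width_mm=1.0, well_radius_mm=10.0)
        expect = 4000 / 10 / 2.0
        assert np.all(np.abs(prof["density_per_mm2"] - expect) / expect < 0.15)

    def test_zero_area_bin_reported_missing(self):
        areas = np.array([1.0, 0.0])
        prof = sw.bin_by_radius(self._records([0.5, 1.5]), areas, 1.0, 2.0)
        assert np.isnan(prof["density_per_mm2"][1])
        assert prof["count"][1] == 1

    def test_last_bin_closed_at_wall(self):
        prof = sw.bin_by_radius(self._records([17.4]), 1.0, 1.0, 17.4)
        assert prof["count"].iloc[-1] == 1


class TestAggregateProfiles:
    def test_sem_over_wells_from_per_well_means(self):
        p1 = sw.bin_by_radius(
            TestBinByRadius()._records([0.5, 0.5], si=0.8), 1.0, 1.0, 2.0
        )
        p2 = sw.bin_by_radius(
            TestBinByRadius()._records([0.5, 0.5, 0.5], si=0.6), 1.0, 1.0, 2.0
        )
        agg = sw.aggregate_profiles([p1, p2])
        assert agg["si_mean"][0] == pytest.approx(0.7)
        expected_sem = np.std([0.8, 0.6], ddof=1) / np.sqrt(2)
        assert agg["si_sem"][0] == pytest.approx(expected_sem)

    def test_single_well_sem_is_missing(self):
        p1 = sw.bin_by_radius(TestBinByRadius()._records([0.5]), 1.0, 1.0, 2.0)
        agg = sw.aggregate_profiles([p1])
        assert np.isnan(agg["si_sem"][0])


class TestOrientationProfileFit:
    def _profile(self, r, y):
        return pd.DataFrame(
            {"r_mid_mm": r, "orientation_mode_deg": y,
             "orientation_sem_deg": np.ones_like(r)}
        )

    def test_low_degree_polynomial_recovered_exactly(self):
        r = np.arange(12, dtype=float) + 0.5
        y = 1.0 - 2.0 * r + 0.3 * r**2 - 0.01 * r**3
        fit = sw.fit_orientation_profile(self._profile(r, y))
        assert fit.degree == 7
        assert np.allclose(fit(r), y, atol=1e-6)

    def test_constant_plus_noise_stays_within_band(self):
        rng = np.random.default_rng(5)
        r = np.arange(15, dtype=float) + 0.5
        y = 45.0 + rng.normal(0, 1.0, len(r))
        fit = sw.fit_orientation_profile(self._profile(r, y))
        assert np.all(np.abs(fit(r) - 45.0) < 2 * 2.0)

    def test_degree_reduced_for_few_bins(self):
        r = np.arange(5, dtype=float)
        with pytest.warns(UserWarning, match="reducing"):
            fit = sw.fit_orientation_profile(self._profile(r, r * 2.0))
        assert fit.degree == 3
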