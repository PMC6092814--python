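"""Synthetic-data generator: determinism, z-stacks, waveforms, feasibility."""

import numpy as np
import pytest

import swirlwell as sw


class TestDeterminism:
    def test_identical_seeds_bit_identical(self):
        spec = sw.SyntheticWellSpec(seed=9)
        f1, t1, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.4)
        f2, t2, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.4)
        assert np.array_equal(f1.pixels, f2.pixels)
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        spec = sw.SyntheticWellSpec(seed=9)
        f1, _, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.4)
        f2, _, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.4,
                                          seed=10)
        assert not np.array_equal(f1.pixels, f2.pixels)

    def test_wss_series_deterministic(self):
        s1 = sw.generate_wss_series("random", seed=4)
        s2 = sw.generate_wss_series("random", seed=4)
        assert np.array_equal(s1.vectors, s2.vectors)


class TestZStack:
    def test_single_slice_equals_flat_image(self):
        spec = sw.SyntheticWellSpec(seed=5)
        f1, t1, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.35)
        f2, t2, _ = sw.generate_zstack(spec, n_slices=1, kind="disc",
                                       disc_radius_mm=0.35)
        assert np.array_equal(np.squeeze(f1.pixels), np.squeeze(f2.pixels))
        assert len(t1) == len(t2)

    def test_projection_recovers_all_nuclei(self):
        spec = sw.SyntheticWellSpec(seed=6)
        stack, truth, _ = sw.generate_zstack(spec, n_slices=43, kind="disc",
                                             disc_radius_mm=0.4)
        assert stack.n_slices == 43
        proj = sw.max_projection(stack)
        det = sw.segment_nuclei(proj)
        assert len(det) == len(truth)

    def test_projection_dominates_single_slices(self):
        spec = sw.SyntheticWellSpec(seed=6)
        stack, truth, _ = sw.generate_zstack(spec, n_slices=12, kind="disc",
                                             disc_radius_mm=0.4)
        proj_count = len(sw.segment_nuclei(sw.max_projection(stack)))
        slice_counts = [
            len(
                sw.segment_nuclei(
                    sw.ImageFrame(stack.pixels[k], stack.pixel_size_um,
                                  stack.well_centre_px)
                )
            )
            for k in range(stack.n_slices)
        ]
        assert proj_count >= max(slice_counts)
        # defocused nuclei are genuinely missed slice by slice
        assert min(slice_counts) < len(truth)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError):
            sw.generate_zstack(sw.SyntheticWellSpec(), n_slices=0)


class TestPlacementFeasibility:
    def test_impossible_density_rejected_with_estimate(self):
        spec = sw.SyntheticWellSpec(seed=1, density_centre_per_mm2=6000,
                                    density_edge_per_mm2=6000)
        with pytest.raises(ValueError, match="cells/mm"):
            sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.4)

    def test_isotropic_spec_gives_round_unaligned_nuclei(self):
        spec = sw.SyntheticWellSpec(seed=2, axis_ratio_centre=1.0,
                                    axis_ratio_edge=1.0, kappa_centre=0.0,
                                    kappa_edge=0.0)
        _, truth, _ = sw.generate_well_image(spec, kind="disc", disc_radius_mm=0.5)
        assert np.allclose(truth["si"], 1.0)
        # orientations roughly uniform: axial resultant length near zero
        ang = np.deg2rad(truth["orientation_deg"].to_numpy()) * 2
        resultant = np.hypot(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        assert resultant < 0.15


class TestAdhesionGenerator:
    def test_effect_table(self):
        spec = sw.SyntheticWellSpec()
        base_c = sw.expected_adhesion_ratio(spec, "untreated", False, "centre")
        base_e = sw.expected_adhesion_ratio(spec, "untreated", False, "edge")
        assert base_c > base_e  # centre more adhesive under multidirectional flow
        assert sw.expected_adhesion_ratio(spec, "tnf", False, "centre") == pytest.approx(
            base_c * spec.tnf_multiplier
        )
        # the segmentation effect applies at the centre under TNF-alpha only
        assert sw.expected_adhesion_ratio(spec, "tnf", True, "centre") == pytest.approx(
            base_c * spec.tnf_multiplier * spec.segmentation_centre_effect
        )
        assert sw.expected_adhesion_ratio(spec, "tnf", True, "edge") == pytest.approx(
            sw.expected_adhesion_ratio(spec, "tnf", False, "edge")
        )
        assert sw.expected_adhesion_ratio(spec, "untreated", True, "centre") == pytest.approx(
            base_c
        )

    def test_doubling_density_doubles_expected_counts(self):
        spec = sw.SyntheticWellSpec(seed=8)
        double = sw.SyntheticWellSpec(
            seed=8,
            adhesion_base_ratio_centre=2 * spec.adhesion_base_ratio_centre,
        )
        _, t1 = sw.generate_adhesion_images(spec, "untreated", False, "centre",
                                            n_fields=6, seed=8)
        _, t2 = sw.generate_adhesion_images(double, "untreated", False, "centre",
                                            n_fields=6, seed=8)
        assert t2["expected_ratio"][0] == pytest.approx(2 * t1["expected_ratio"][0])


class TestWaveforms:
    def test_rotating_closed_forms_attached(self):
        _, expected = sw.analytic_waveform("rotating", tau0=0.3)
        assert expected == pytest.approx(
            {"tawss": 0.3, "osi": 0.5, "transwss": 2 * 0.3 / np.pi}
        )

    def test_uniaxial_constant_vector(self):
        series = sw.generate_wss_series("uniaxial_constant", tau0=0.7)
        assert np.allclose(series.vectors[0, :, 0], 0.7)
        assert np.allclose(series.vectors[0, :, 1:], 0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sw.analytic_waveform("spiral")
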