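"""Shear-metric integrals against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swirlwell as sw
from oracles import riemann_metrics

TAU0 = 0.3
PERIOD = 0.4


def random_series(seed: int, samples_per_cycle: int = 64):
    f, _ = sw.analytic_waveform("random", seed=seed, tau0=TAU0, period_s=PERIOD)
    series = sw.generate_wss_series(
        "random", samples_per_cycle=samples_per_cycle, seed=seed,
        tau0=TAU0, period_s=PERIOD,
    )
    return f, series


class TestClosedForms:
    @pytest.mark.parametrize(
        "kind,expected",
        [
            ("uniaxial_constant", {"tawss": TAU0, "osi": 0.0, "transwss": 0.0}),
            ("rotating", {"tawss": TAU0, "osi": 0.5, "transwss": 2 * TAU0 / np.pi}),
            ("uniaxial_sin", {"tawss": 2 * TAU0 / np.pi, "osi": 0.5, "transwss": 0.0}),
            ("reversing", {"tawss": 0.75, "osi": 1.0 / 3.0, "transwss": 0.0}),
        ],
    )
    def test_matches_analytic_values(self, kind, expected):
        series = sw.generate_wss_series(kind, tau0=TAU0, period_s=PERIOD)
        field = sw.compute_metrics(series)
        for name, val in expected.items():
            got = getattr(field, name)[0]
            if val == 0.0:
                assert got == pytest.approx(0.0, abs=1e-9)
            else:
                assert got == pytest.approx(val, rel=1e-3)

    def test_mixed_waveform_transwss(self):
        # mean shear plus a small orthogonal sinusoid: transWSS = 2*eps/pi
        eps = 0.02
        series = sw.generate_wss_series("mixed", mean=0.5, eps=eps, period_s=PERIOD)
        field = sw.compute_metrics(series)
        assert field.transwss[0] == pytest.approx(2 * eps / np.pi, rel=1e-3)
        assert not field.degenerate_mean[0]

    def test_rotating_transwss_axis_independent(self):
        # degenerate mean: result must not depend on the waveform phase
        vals = [
            sw.compute_metrics(
                sw.generate_wss_series("rotating", tau0=TAU0, phase0=ph)
            ).transwss[0]
            for ph in np.linspace(0, 2 * np.pi, 9)
        ]
        assert np.ptp(vals) < 1e-9
        assert vals[0] == pytest.approx(2 * TAU0 / np.pi, rel=1e-3)

    def test_rotating_is_flagged_degenerate(self):
        field = sw.compute_metrics(sw.generate_wss_series("rotating"))
        assert field.degenerate_mean[0]
        assert np.linalg.norm(field.mean_vector[0]) < 1e-12


class TestAgainstOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_series_match_riemann_oracle(self, seed):
        # 256 samples/cycle: the trapezoid error of the smooth random
        # waveforms is then well inside the 1e-3 comparison tolerance
        f, series = random_series(seed, samples_per_cycle=256)
        field = sw.compute_metrics(series)
        oracle = riemann_metrics(f, PERIOD)
        assert field.tawss[0] == pytest.approx(oracle["tawss"], rel=1e-3)
        assert field.osi[0] == pytest.approx(oracle["osi"], rel=1e-3, abs=1e-6)
        assert field.transwss[0] == pytest.approx(oracle["transwss"], rel=1e-3)

    @pytest.mark.parametrize("seed", [3, 11, 17])
    def test_quadrature_convergence(self, seed):
        # smooth waveforms: refining 64 -> 256 samples must not increase
        # the quadrature error
        f, coarse = random_series(seed, samples_per_cycle=64)
        _, fine = random_series(seed, samples_per_cycle=256)
        oracle = riemann_metrics(f, PERIOD)
        for compute in (sw.compute_tawss, sw.compute_osi):
            name = "tawss" if compute is sw.compute_tawss else "osi"
            err_c = abs(compute(coarse)[0] - oracle[name])
            err_f = abs(compute(fine)[0] - oracle[name])
            assert err_f <= err_c + 1e-9
            assert err_f <= 2e-3 * max(abs(oracle[name]), 1.0)


class TestProperties:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_bounds_hold_for_random_series(self, seed):
        _, series = random_series(seed)
        field = sw.compute_metrics(series)
        assert field.tawss[0] >= 0
        assert 0 <= field.osi[0] <= 0.5
        assert -1e-12 <= field.transwss[0] <= field.tawss[0] + 1e-12

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10**6), angle=st.floats(0, 2 * np.pi))
    def test_rotation_invariance(self, seed, angle):
        _, series = random_series(seed)
        a = sw.compute_metrics(series)
        b = sw.compute_metrics(series.rotated(angle))
        assert b.tawss[0] == pytest.approx(a.tawss[0], rel=1e-12)
        assert b.osi[0] == pytest.approx(a.osi[0], abs=1e-12)
        assert b.transwss[0] == pytest.approx(a.transwss[0], rel=1e-9, abs=1e-12)


class TestDegenerateAndErrors:
    def test_zero_series_flagged(self):
        series = sw.WSSVectorSeries(
            points=[[0.0, 0.0]],
            times=np.linspace(0, PERIOD, 65),
            vectors=np.zeros((1, 65, 3)),
            period_s=PERIOD,
        )
        field = sw.compute_metrics(series)
        assert field.tawss[0] == 0.0
        assert field.osi[0] == 0.0
        assert field.degenerate_mean[0]

    def test_short_series_rejected(self):
        series = sw.WSSVectorSeries(
            points=[[0.0, 0.0]],
            times=np.linspace(0, PERIOD / 3, 16),
            vectors=np.ones((1, 16, 3)),
            period_s=PERIOD,
        )
        with pytest.raises(ValueError, match="full period"):
            sw.compute_metrics(series)

    def test_non_unit_normal_rejected(self):
        series = sw.generate_wss_series("rotating")
        with pytest.raises(ValueError, match="unit"):
            sw.compute_metrics(series, normal=[0, 0, 2.0])

    def test_longer_series_windowed_to_final_period(self):
        # two cycles where the start is garbage: only the final full
        # period (which begins one sample before the second cycle, the
        # window being closed at the last sample) is integrated
        series = sw.generate_wss_series("rotating", n_cycles=2, tau0=TAU0)
        series.vectors[:, : series.vectors.shape[1] // 2 - 1, :] = 99.0
        field = sw.compute_metrics(series)
        assert field.tawss[0] == pytest.approx(TAU0, rel=1e-3)


class TestRadialProfile:
    def test_uniform_field_is_flat(self):
        pts = [[r, 0.0] for r in np.linspace(0, 10, 11)]
        times = np.linspace(0, PERIOD, 65)
        vecs = np.tile([TAU0, 0.0, 0.0], (len(pts), len(times), 1))
        field = sw.compute_metrics(
            sw.WSSVectorSeries(pts, times, vecs, PERIOD, well_radius_mm=10.0)
        )
        prof = sw.radial_metric_profile(field, 1.0)
        assert np.allclose(prof["tawss_Pa"], TAU0)
        assert np.allclose(prof["osi"], 0.0)

    def test_single_bin_equals_global_mean(self):
        series = sw.synthesize_wss_field(
            sw.WellGeometry(), sw.SurrogateFlowSpec(), n_r=6, n_theta=4
        )
        field = sw.compute_metrics(series)
        prof = sw.radial_metric_profile(field, bin_width_mm=17.4)
        assert len(prof) == 1
        assert prof["tawss_Pa"][0] == pytest.approx(field.tawss.mean())

    def test_empty_bins_reported_missing(self):
        pts = [[0.5, 0.0], [5.5, 0.0]]
        times = np.linspace(0, PERIOD, 65)
        vecs = np.tile([TAU0, 0.0, 0.0], (2, len(times), 1))
        field = sw.compute_metrics(
            sw.WSSVectorSeries(pts, times, vecs, PERIOD, well_radius_mm=6.0)
        )
        prof = sw.radial_metric_profile(field, 1.0)
        assert prof["n_points"].tolist() == [1, 0, 0, 0, 0, 1]
        assert prof["tawss_Pa"].isna().tolist() == [False, True, True, True, True, False]
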